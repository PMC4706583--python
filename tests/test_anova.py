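"""Unequal-size model II ANOVA: scalar oracle, invariances, lineage walk."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clandiv import (
    AnnotatedSequence,
    ClanVarianceModel,
    InputError,
    build_taxonomy,
    distance_matrix,
    partition,
    partition_lineage,
    partitions_frame,
    per_sequence_average,
)
from conftest import make_lineage


def brute_force_partition(values, clans):
    """Independent oracle: naive double-loop sums of squares."""
    groups = {}
    for v, c in zip(values, clans):
        groups.setdefault(c, []).append(v)
    k = len(groups)
    sizes = [len(g) for g in groups.values()]
    N = sum(sizes)
    grand = sum(values) / N
    ss_among = 0.0
    for g in groups.values():
        mean_g = sum(g) / len(g)
        ss_among += len(g) * (mean_g - grand) ** 2
    ss_within = 0.0
    for g in groups.values():
        mean_g = sum(g) / len(g)
        for y in g:
            ss_within += (y - mean_g) ** 2
    ms_among = ss_among / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - sum(n * n for n in sizes) / N) / (k - 1)
    s2a = max(0.0, (ms_among - ms_within) / n0)
    pct = 100 * s2a / (s2a + ms_within) if (s2a + ms_within) > 0 else 0.0
    return dict(
        ss_among=ss_among, ss_within=ss_within, ms_among=ms_among,
        ms_within=ms_within, n0=n0, sigma2_among=s2a, pct_inter=pct,
    )


class TestScalarPartition:
    def test_worked_example(self):
        # {1,2,3} vs {7,8}: all quantities re-derived by hand
        res = partition([1, 2, 3, 7, 8], ["a", "a", "a", "b", "b"])
        assert res.N == 5 and res.k == 2
        assert res.n0 == pytest.approx(2.4)
        assert res.ms_among == pytest.approx(36.3)
        assert res.ms_within == pytest.approx(0.8333, abs=1e-4)
        assert res.sigma2_among == pytest.approx(14.7778, abs=1e-4)
        assert res.pct_inter == pytest.approx(94.66, abs=0.01)
        assert res.pct_intra == pytest.approx(5.34, abs=0.01)

    def test_equal_clan_means_truncate_to_zero(self):
        res = partition([1, 3, 1, 3], ["a", "a", "b", "b"])
        assert res.sigma2_among == 0
        assert res.pct_inter == 0

    def test_equal_sizes_n0_equals_n(self):
        res = partition([1.0, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert res.n0 == pytest.approx(3.0)

    def test_percentages_sum_to_100(self, rng):
        vals = rng.normal(size=30)
        clans = rng.choice(["a", "b", "c"], size=30)
        res = partition(list(vals), list(clans))
        assert res.pct_inter + res.pct_intra == pytest.approx(100.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        sizes = rng.integers(1, 10, size=k)
        while sizes.sum() <= k or (sizes < 2).all():
            sizes = rng.integers(1, 10, size=k)
        values, clans = [], []
        for c, n in enumerate(sizes):
            values.extend(rng.normal(loc=c, size=n))
            clans.extend([f"clan{c}"] * n)
        res = partition(values, clans)
        exp = brute_force_partition(values, clans)
        for key, val in exp.items():
            assert getattr(res, key) == pytest.approx(val, abs=1e-10)

    def test_scale_equivariance(self, rng):
        vals = list(rng.normal(size=20))
        clans = list(rng.choice(["a", "b", "c"], size=20))
        base = partition(vals, clans)
        scaled = partition([3.5 * v for v in vals], clans)
        assert scaled.sigma2_among == pytest.approx(3.5**2 * base.sigma2_among)
        assert scaled.sigma2_within == pytest.approx(3.5**2 * base.sigma2_within)
        assert scaled.pct_inter == pytest.approx(base.pct_inter)

    def test_translation_invariance(self, rng):
        vals = list(rng.normal(size=20))
        clans = list(rng.choice(["a", "b"], size=20))
        base = partition(vals, clans)
        shifted = partition([v + 17.0 for v in vals], clans)
        assert shifted.sigma2_among == pytest.approx(base.sigma2_among, abs=1e-9)
        assert shifted.pct_inter == pytest.approx(base.pct_inter, abs=1e-6)

    def test_singleton_clan_allowed(self):
        res = partition([1.0, 5, 6, 7], ["solo", "b", "b", "b"])
        assert res.sizes == [3, 1] or res.sizes == [1, 3]
        assert res.df_within == 2

    @pytest.mark.parametrize(
        "values,clans",
        [
            ([1, 2], ["a", "a"]),              # one clan
            ([1, 2], ["a", "b"]),              # N == k
            ([1, 2, 3], ["a", "b", "c"]),      # all singletons
        ],
    )
    def test_precondition_violations_raise(self, values, clans):
        with pytest.raises(InputError):
            partition(values, clans)

    def test_null_calibration_median_below_15_percent(self):
        # clans drawn i.i.d. from one pool: sigma2_among expectation is 0;
        # the median percentage over replicates stays small
        rng = np.random.default_rng(2024)
        pcts = []
        for _ in range(1000):
            vals = rng.normal(size=24)
            clans = np.repeat(["a", "b", "c", "d"], 6)
            pcts.append(partition(list(vals), list(clans)).pct_inter)
        assert np.median(pcts) < 15.0

    def test_recovery_of_known_variance_ratio(self):
        # sigma2_A = 4, sigma2_W = 1 -> truth 80%; N = 200 per replicate
        rng = np.random.default_rng(77)
        truth = 100 * 4 / (4 + 1)
        estimates = []
        for _ in range(30):
            k, n = 20, 10
            effects = rng.normal(scale=2.0, size=k)
            vals, clans = [], []
            for c in range(k):
                vals.extend(effects[c] + rng.normal(size=n))
                clans.extend([f"c{c}"] * n)
            estimates.append(partition(vals, clans).pct_inter)
        est = np.mean(estimates)
        mc_sd = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(est - truth) < 3 * max(mc_sd, 1e-6) + 1.0

    def test_summary_renders(self):
        res = partition([1, 2, 3, 7, 8], ["a", "a", "a", "b", "b"])
        text = res.summary()
        assert "94.66" in text and "n0" in text

    def test_from_dataframe(self):
        df = pd.DataFrame({"value": [1, 2, 3, 7, 8],
                           "clan": ["a", "a", "a", "b", "b"]})
        res = ClanVarianceModel.from_dataframe(df).fit()
        assert res.pct_inter == pytest.approx(94.66, abs=0.01)


def _two_phylum_family(
    d_between, d_within, length=400, seed=3, organisms=(2, 8), hgt=0
):
    """Two-phylum alignment with controlled divergence and uneven clan sizes.

    Clan sizes are drawn unequal on purpose: the per-sequence average
    p-distance carries the between-clan signal through the asymmetry of
    cross-clan pair counts, which is exactly the unequal-size setting the
    variance partition targets (a perfectly balanced two-clan split has
    identical clan means by symmetry).
    """
    from clandiv import SimulationConfig, simulate_family

    cfg = SimulationConfig(
        seq_length=length,
        branching={
            "kingdom": (1, 1), "phylum": (2, 2), "class": (1, 1),
            "order": (1, 1), "family": (1, 1), "genus": (1, 3),
            "organism": organisms,
        },
        rate_per_rank={
            "kingdom": 0.0, "phylum": d_between, "class": 0.0, "order": 0.0,
            "family": 0.0, "genus": 0.0, "organism": d_within,
        },
        seed=seed,
        hgt_events=hgt,
        hgt_rank="phylum",
    )
    return simulate_family(cfg)


def _phylum_pct_inter(seqs):
    tax = build_taxonomy(seqs)
    M = distance_matrix(seqs)
    parts = partitions_frame(partition_lineage(M, tax))
    row = parts[(parts["child_rank"] == "phylum") & (parts["status"] == "ok")]
    assert len(row) == 1
    return float(row["pct_inter"].iloc[0])


class TestLineagePartition:
    def test_strong_between_phylum_divergence_dominates(self):
        seqs, _, _ = _two_phylum_family(d_between=1.2, d_within=0.02)
        assert _phylum_pct_inter(seqs) > 90

    def test_hgt_monotonically_depresses_inter_clan_share(self):
        # whole-sequence cross-phylum transfers plant within-clan outliers,
        # so the inter-clan share must fall as events accumulate
        means = []
        for hgt in (0, 2, 4):
            vals = [
                _phylum_pct_inter(
                    _two_phylum_family(
                        0.8, 0.05, seed=100 + s, organisms=(3, 8), hgt=hgt
                    )[0]
                )
                for s in range(6)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_null_split_gives_small_inter_share(self):
        # no phylum-level divergence: the split is arbitrary labelling
        pcts = []
        for seed in range(8):
            seqs, _, _ = _two_phylum_family(
                d_between=0.0, d_within=0.3, seed=seed
            )
            tax = build_taxonomy(seqs)
            M = distance_matrix(seqs)
            parts = partitions_frame(partition_lineage(M, tax))
            row = parts[
                (parts["child_rank"] == "phylum") & (parts["status"] == "ok")
            ]
            pcts.append(float(row["pct_inter"].iloc[0]))
        assert np.median(pcts) < 15.0

    def test_singleton_child_node_matches_scalar_brute_force(self):
        mk = make_lineage
        residues = {
            "a1": "AAAAAAAAAA", "a2": "AAAAAAAACC", "a3": "AACCCCAACC",
            "b1": "CCCCAAAAAA",
        }
        seqs = [
            AnnotatedSequence("a1", residues["a1"], mk(genus="G1", organism="o1")),
            AnnotatedSequence("a2", residues["a2"], mk(genus="G1", organism="o2")),
            AnnotatedSequence("a3", residues["a3"], mk(genus="G1", organism="o3")),
            AnnotatedSequence("b1", residues["b1"], mk(genus="G2", organism="o4")),
        ]
        tax = build_taxonomy(seqs)
        M = distance_matrix(seqs)
        parts = partition_lineage(M, tax)
        fam = [p for p in parts if p.child_rank == "genus" and p.status == "ok"]
        assert len(fam) == 1
        res = fam[0].results
        assert res.df_within == 2
        values = per_sequence_average(M, [s.accession for s in seqs])
        clans = {"a1": "G1", "a2": "G1", "a3": "G1", "b1": "G2"}
        exp = brute_force_partition(
            [values[a] for a in sorted(values)], [clans[a] for a in sorted(values)]
        )
        assert res.pct_inter == pytest.approx(exp["pct_inter"], abs=1e-10)

    def test_ineligible_nodes_reported_with_reason(self):
        seqs = [
            AnnotatedSequence("a", "ACDE", make_lineage(organism="o1")),
            AnnotatedSequence("b", "ACDF", make_lineage(organism="o2")),
        ]
        tax = build_taxonomy(seqs)
        M = distance_matrix(seqs)
        parts = partition_lineage(M, tax)
        assert parts and all(p.status != "ok" for p in parts)
        assert all(p.results is None for p in parts)

    def test_pairwise_observation_variant_runs(self):
        seqs, _, _ = _two_phylum_family(d_between=0.8, d_within=0.05)
        tax = build_taxonomy(seqs)
        M = distance_matrix(seqs)
        parts = partition_lineage(M, tax, observation="pairwise")
        assert any(p.status == "ok" for p in parts)
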