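"""Lead-variant selection: LD source invariants, greedy clumping against
an exhaustive pairwise oracle, positional gene mapping and the two-stage
look-up analysis."""

import logging

import numpy as np
import pandas as pd
import pytest

from agescan.leads import (
    GeneInterval,
    LDSource,
    clump,
    lookup_interactions,
    map_genes,
    read_bed,
)
from agescan.phenoprep import preprocess
from agescan.scan import InteractionScan, ScanConfig
from agescan.simulate import SimulationSpec, simulate_cohort, simulate_genotypes

from conftest import make_variants


def rows_frame(ids, pvals, betas=None, chrom="1", trait="apob"):
    m = len(ids)
    return pd.DataFrame(
        {
            "SNPID": ids,
            "CHR": [chrom] * m,
            "POS": np.arange(100, 100 + m),
            "Non_Effect_Allele": ["G"] * m,
            "Effect_Allele": ["A"] * m,
            "N": [1000] * m,
            "EAF": [0.3] * m,
            "Beta_GxAge": betas if betas is not None else np.zeros(m),
            "SE_GxAge": np.ones(m),
            "P_Int": pvals,
            "trait": [trait] * m,
        }
    )


def brute_force_clump(rows, r2, r2_max, p_max, p_col="P_Int"):
    """Independent reference: explicit loops over all pairwise constraints."""
    sig = rows[rows[p_col] < p_max]
    order = sig.sort_values(
        [p_col, "POS"], kind="mergesort"
    )  # ties impossible in these fixtures beyond position
    ids = list(order["SNPID"])
    leads, assigned = [], {}
    for vid in ids:
        if vid in assigned:
            continue
        leads.append(vid)
        for other in ids:
            if other not in assigned and other != vid and r2[(vid, other)] >= r2_max:
                assigned[other] = vid
    return leads, assigned


class TestLDSource:
    def test_self_r2_is_one_and_symmetric(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.3, size=(5, 500)).astype(float)
        from test_scan import block_from_dosages

        ld = LDSource.from_genotypes(block_from_dosages(dos))
        assert ld.r2("v0", "v0") == 1.0
        for a, b in [("v0", "v1"), ("v2", "v4")]:
            assert ld.r2(a, b) == pytest.approx(ld.r2(b, a), rel=1e-12)
            assert 0.0 <= ld.r2(a, b) <= 1.0

    def test_unknown_variant_independent_with_warning(self, caplog):
        ld = LDSource.from_matrix(["v0"], np.array([[1.0]]))
        with caplog.at_level(logging.WARNING):
            assert ld.r2("v0", "missing") == 0.0
        assert "absent" in caplog.text


class TestClump:
    def test_single_significant_variant_is_sole_lead(self):
        rows = rows_frame(["v0", "v1"], [1e-10, 0.5])
        ld = LDSource.from_matrix(["v0", "v1"], np.eye(2))
        leads = clump(rows, ld, r2_max=0.1, p_max=1e-8)
        assert len(leads) == 1 and leads[0].id == "v0" and leads[0].members == []

    def test_perfect_ld_pair_collapses_to_best_p(self):
        rows = rows_frame(["a", "b"], [1e-9, 1e-10])
        r2 = np.array([[1.0, 1.0], [1.0, 1.0]])
        leads = clump(rows, LDSource.from_matrix(["a", "b"], r2), r2_max=0.1, p_max=1e-8)
        assert len(leads) == 1
        assert leads[0].id == "b" and leads[0].members == ["a"]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(1)
        m = 30
        corr = np.clip(rng.uniform(0, 0.4, (m, m)), 0, 1)
        r2 = (corr + corr.T) / 2
        np.fill_diagonal(r2, 1.0)
        pvals = rng.uniform(1e-12, 1e-9, m)
        ids = [f"v{i}" for i in range(m)]
        rows = rows_frame(ids, pvals)
        ld = LDSource.from_matrix(ids, r2)
        a = clump(rows, ld, 0.1, 1e-8)
        shuffled = rows.sample(frac=1.0, random_state=7).reset_index(drop=True)
        b = clump(shuffled, ld, 0.1, 1e-8)
        assert [l.id for l in a] == [l.id for l in b]
        assert [sorted(l.members) for l in a] == [sorted(l.members) for l in b]

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_matches_exhaustive_pairwise_oracle(self, seed):
        """Greedy clumping of a simulated 200-variant LD block equals an
        independently coded all-pairs reference, and retained leads are
        mutually below the r² bound."""
        spec = SimulationSpec(
            n_individuals=2000,
            seed=seed,
            variants=make_variants(200),
            ld_blocks=[(0, 200, 0.9)],
        )
        geno = simulate_genotypes(spec)
        rng = np.random.default_rng(seed + 1)
        pvals = 10.0 ** rng.uniform(-16, -9, 200)
        ids = list(geno.variants["id"])
        rows = rows_frame(ids, pvals)
        rows["POS"] = geno.variants["pos"].to_numpy()
        ld = LDSource.from_genotypes(geno)
        leads = clump(rows, ld, r2_max=0.1, p_max=1e-8)

        r2_full = np.corrcoef(geno.dosages) ** 2
        r2_map = {
            (a, b): r2_full[i, j]
            for i, a in enumerate(ids)
            for j, b in enumerate(ids)
        }
        oracle_leads, oracle_assigned = brute_force_clump(rows, r2_map, 0.1, 1e-8)
        assert [l.id for l in leads] == oracle_leads
        got_assignment = {m: l.id for l in leads for m in l.members}
        assert got_assignment == oracle_assigned
        # partition: every significant row is a lead or exactly one member
        assert len(got_assignment) + len(leads) == 200
        # pairwise independence of retained leads
        lead_idx = [ids.index(l.id) for l in leads]
        sub = r2_full[np.ix_(lead_idx, lead_idx)]
        np.fill_diagonal(sub, 0.0)
        assert sub.max() < 0.1


class TestGeneMapping:
    GENES = [
        GeneInterval("INSIDE", "1", 500, 1500),
        GeneInterval("NEAR", "1", 11_001, 12_000),
        GeneInterval("FAR", "1", 11_002, 12_000),
        GeneInterval("OTHER_CHR", "2", 900, 1200),
    ]

    def lead_at(self, pos):
        rows = rows_frame(["v0"], [1e-10])
        rows["POS"] = pos
        ld = LDSource.from_matrix(["v0"], np.eye(1))
        return clump(rows, ld, 0.1, 1e-8)[0]

    def test_variant_inside_gene_distance_zero(self):
        lead = map_genes([self.lead_at(1000)], self.GENES, 10_000)[0]
        assert ("INSIDE", 0) in lead.genes
        assert all(g != "OTHER_CHR" for g, _ in lead.genes)

    def test_boundary_inclusive_at_max_dist(self):
        lead = map_genes([self.lead_at(1001)], self.GENES, 10_000)[0]
        names = [g for g, _ in lead.genes]
        assert "NEAR" in names  # exactly 10,000 bp away
        assert "FAR" not in names  # 10,001 bp away
        assert dict(lead.genes)["NEAR"] == 10_000

    def test_no_gene_in_range_gives_empty_list(self):
        lead = map_genes([self.lead_at(10_000_000)], self.GENES, 10_000)[0]
        assert lead.genes == []

    def test_bed_half_open_converted_to_one_based_inclusive(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t999\t2000\tGENE1\n#comment\n2\t0\t10\tGENE2\n")
        genes = read_bed(bed)
        assert genes[0].start == 1000 and genes[0].end == 2000
        assert genes[1].start == 1 and genes[1].end == 10
        # a variant at the first base of GENE1 is inside it
        assert genes[0].distance_to("1", 1000) == 0
        assert genes[0].distance_to("1", 999) == 1


class TestLookup:
    def test_threshold_is_alpha_over_lead_count(self):
        ids = [f"v{i}" for i in range(145)]
        rows = rows_frame(ids, [1e-10] * 145)
        ld = LDSource.from_matrix(ids, np.eye(145))
        leads = {"apob": clump(rows, ld, 0.1, 1e-8)}
        report = lookup_interactions(leads, rows, alpha=0.05)
        assert len(report) == 145
        assert report["threshold"].iloc[0] == pytest.approx(0.05 / 145)

    def test_single_lead_threshold_is_alpha(self):
        rows = rows_frame(["v0"], [1e-10], trait="tg")
        ld = LDSource.from_matrix(["v0"], np.eye(1))
        report = lookup_interactions({"tg": clump(rows, ld, 0.1, 1e-8)}, rows, 0.05)
        assert report["threshold"].iloc[0] == 0.05

    def test_thresholds_monotone_in_lead_count(self):
        thresholds = []
        for k in (1, 5, 50):
            ids = [f"v{i}" for i in range(k)]
            rows = rows_frame(ids, [1e-10] * k)
            ld = LDSource.from_matrix(ids, np.eye(k))
            rep = lookup_interactions({"apob": clump(rows, ld, 0.1, 1e-8)}, rows, 0.05)
            thresholds.append(rep["threshold"].iloc[0])
        assert thresholds[0] > thresholds[1] > thresholds[2]

    def test_zero_leads_empty_report(self):
        rows = rows_frame(["v0"], [0.5])
        report = lookup_interactions({"apob": []}, rows, 0.05)
        assert report.empty

    def test_high_power_truth_recovered(self):
        """With 3 of 20 marginal leads carrying a strong true interaction,
        the look-up report flags exactly those 3."""
        causal = {0, 7, 15}
        beta_g = {i: {"apob": 0.25} for i in range(20)}
        beta_gxage = {i: {"apob": 0.012} for i in causal}
        spec = SimulationSpec(
            n_individuals=6000,
            seed=55,
            variants=make_variants(20, beta_g=beta_g, beta_gxage=beta_gxage),
        )
        geno, pheno, _ = simulate_cohort(spec)
        results = InteractionScan(geno, preprocess(pheno), traits=["apob"]).fit()
        ld = LDSource.from_genotypes(geno)
        marg = {"apob": results.clump(ld, "apob", kind="marginal")}
        assert len(marg["apob"]) == 20  # unlinked, all genome-wide marginal
        report = lookup_interactions(marg, results.table, 0.05)
        hits = set(report.loc[report["significant"], "RSID"])
        assert hits == {f"rs{i}" for i in causal}
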