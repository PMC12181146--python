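import numpy as np
import pytest

from agescan.simulate import MedicationModel, SimulationSpec, VariantSpec, simulate_cohort


def make_variants(n, maf=0.3, chrom="1", start=100_000, step=5_000, **effects):
    return [
        VariantSpec(
            id=f"rs{i}",
            chrom=chrom,
            pos=start + i * step,
            maf=maf if np.isscalar(maf) else maf[i],
            beta_g=effects.get("beta_g", {}).get(i, {}),
            beta_gxage=effects.get("beta_gxage", {}).get(i, {}),
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A 1,500-person cohort with one ApoB interaction variant and one
    marginal-only LDL variant; shared across read-only tests."""
    spec = SimulationSpec(
        n_individuals=1500,
        seed=42,
        variants=make_variants(
            10,
            beta_g={0: {"apob": 0.05}, 3: {"ldl": 0.3}},
            beta_gxage={0: {"apob": 0.01}},
        ),
        ld_blocks=[(5, 9, 0.8)],
    )
    geno, pheno, truth = simulate_cohort(spec)
    return spec, geno, pheno, truth


def align_dosages(geno, pheno_df):
    """Genotype columns reordered to match a phenotype table's rows."""
    pos = {s: i for i, s in enumerate(geno.samples)}
    idx = [pos[s] for s in pheno_df["sample_id"]]
    return geno.dosages[:, idx]
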