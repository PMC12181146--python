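"""Default small synthetic-cohort configuration for smoke runs.

A desk-scale cohort: 2,000 individuals aged 40-70, 60 variants including
one LD block of 20 correlated variants, one strong ApoB interaction
variant, one TG interaction variant (attenuating with age) and one
marginal-only LDL variant, so every pipeline stage has work to do.
"""

from __future__ import annotations

from .io import AnalysisConfig


def default_simulation_dict(n_individuals: int = 2000) -> dict:
    variants = []
    for j in range(60):
        v = {
            "id": f"rs{1000 + j}",
            "chrom": "1" if j < 30 else "2",
            "pos": 100_000 + 5_000 * (j % 30),
            "effect_allele": "A",
            "non_effect_allele": "G",
            "maf": 0.05 + 0.4 * ((j * 37) % 30) / 30.0,
            "beta_g": {},
            "beta_gxage": {},
        }
        variants.append(v)
    # causal architecture: strong interaction on apob, attenuating TG
    # effect, marginal-only LDL effect inside the LD block
    # effects sized for clear detection at the desk-scale default n
    variants[5]["beta_g"] = {"apob": 0.05}
    variants[5]["beta_gxage"] = {"apob": 0.008}
    variants[40]["beta_g"] = {"tg": 0.55}
    variants[40]["beta_gxage"] = {"tg": -0.024}
    variants[12]["beta_g"] = {"ldl": 0.25}
    return {
        "n_individuals": n_individuals,
        "variants": variants,
        "ld_blocks": [[10, 30, 0.8]],
        "missingness": {"sbp": 0.01, "tg": 0.01},
    }


def default_pipeline_config(seed: int, n_individuals: int = 2000) -> AnalysisConfig:
    return AnalysisConfig(seed=seed, simulate=default_simulation_dict(n_individuals))
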