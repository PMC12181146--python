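"""Readers, writers, configuration and the end-to-end pipeline runner.

Formats: VCF v4.2 (DS and GT fields; DS preferred on read) via cyvcf2, a
plain dosage-matrix TSV, the phenotype/covariate TSV dialect, GEM-style
per-trait results TSVs whose ``#``-prefixed header lines record the
configuration and seed, and a truth TSV for simulated cohorts. All text
output is tab-delimited UTF-8 with Unix newlines; floats are written with
12 significant digits so round trips are lossless at that precision.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import PC_COLUMNS, TRAITS, GenotypeBlock, PhenotypeTable
from .exceptions import SchemaError
from .phenoprep import DEFAULT_AGE_BINS, PrepConfig
from .scan import RESULT_COLUMNS, ScanConfig

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "read_results",
    "write_results",
    "write_truth",
    "run_pipeline",
]

_FLOAT_FMT = "%.17g"  # full double precision; round trips exact


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """All pipeline constants in one place, serialised into every output.

    Defaults are the standard analysis constants: statin LDL-C divisor
    0.7, +10 mmHg SBP correction, 6-SD winsorization, MAF cutoff 0.001,
    genome-wide alpha 5e-8 Bonferroni-divided by 5 traits (1e-8 per
    trait), clumping r² bound 0.1, look-up alpha 0.05 and 10 kb gene
    mapping. ``seed`` is mandatory for any stochastic stage.
    """

    seed: int | None = None
    # phenotype preprocessing
    statin_ldl_divisor: float = 0.7
    bp_med_sbp_addition: float = 10.0
    winsor_k: float = 6.0
    tg_log: bool = True
    # scan
    maf_min: float = 0.001
    genomewide_alpha: float = 5e-8
    n_traits: int = 5
    se_type: str = "model"
    block_size: int = 512
    # clumping / look-up / genes
    clump_r2_max: float = 0.1
    lookup_alpha: float = 0.05
    gene_max_dist: int = 10_000
    age_bins: tuple = DEFAULT_AGE_BINS
    # simulation (pipeline runs that start from a synthetic cohort)
    simulate: dict = field(default_factory=dict)
    genes_bed: str | None = None

    def prep_config(self) -> PrepConfig:
        return PrepConfig(
            statin_ldl_divisor=self.statin_ldl_divisor,
            bp_med_sbp_addition=self.bp_med_sbp_addition,
            winsor_k=self.winsor_k,
            tg_log=self.tg_log,
        )

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            maf_min=self.maf_min,
            models="both",
            se_type=self.se_type,
            block_size=self.block_size,
            alpha=self.genomewide_alpha,
            n_traits=self.n_traits,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_bins"] = [list(b) for b in self.age_bins]
        return d

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "age_bins" in raw:
            raw["age_bins"] = tuple(tuple(b) for b in raw["age_bins"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(block: GenotypeBlock, path) -> None:
    """Write a dosage VCF v4.2 with GT (hard calls where integral) and DS."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description='
            '"Effect-allele dosage in [0,2]">\n'
        )
        fh.write(f"##source=agescan {__version__}\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(block.samples)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(block.n_variants):
            v = block.variants.iloc[j]
            cells = []
            for d in block.dosages[j]:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    gt = gt_map.get(float(d), "./.")
                    cells.append(f"{gt}:{d:g}")
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{v['id']}\t"
                f"{v['non_effect_allele']}\t{v['effect_allele']}\t.\t.\t.\t"
                "GT:DS\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path, block_size: int = 512):
    """Yield :class:`GenotypeBlock` objects from a VCF.

    DS is preferred over GT when both are present; multi-allelic records
    are skipped with a warning. Positions are 1-based as in the file.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, metas = [], []

    def flush():
        nonlocal rows, metas
        if rows:
            yield GenotypeBlock(
                dosages=np.array(rows, dtype=float),
                variants=pd.DataFrame(metas),
                samples=samples,
            )
            rows, metas = [], []

    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic record {rec.ID or rec.POS} "
                f"({rec.REF}->{','.join(rec.ALT)})",
                stacklevel=2,
            )
            continue
        ds = None
        try:
            ds_arr = rec.format("DS")
        except Exception:
            ds_arr = None
        if ds_arr is not None:
            ds = np.asarray(ds_arr, dtype=float).reshape(-1)
        else:
            ds = np.empty(len(samples))
            for i, g in enumerate(rec.genotypes):
                a = [x for x in g[:-1] if x is not None]
                ds[i] = np.nan if (not a or min(a) < 0) else float(sum(1 for x in a if x == 1))
        rows.append(ds)
        metas.append(
            {
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "non_effect_allele": rec.REF,
                "effect_allele": rec.ALT[0],
            }
        )
        if len(rows) >= block_size:
            yield from flush()
    yield from flush()


def read_genotypes(path, fmt: str | None = None, block_size: int = 512):
    """Dispatch on format: 'vcf' or 'dosage-tsv' (inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "dosage-tsv"
    if fmt == "vcf":
        yield from read_vcf(path, block_size=block_size)
    elif fmt == "dosage-tsv":
        yield read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# dosage / phenotype / truth TSVs
# ---------------------------------------------------------------------------

_DOSAGE_META = ["id", "chrom", "pos", "non_effect_allele", "effect_allele"]


def write_dosage_tsv(block: GenotypeBlock, path) -> None:
    meta = block.variants[_DOSAGE_META].copy()
    mat = pd.DataFrame(block.dosages, columns=block.samples)
    pd.concat([meta, mat], axis=1).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA",
        lineterminator="\n",
    )


def read_dosage_tsv(path) -> GenotypeBlock:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in _DOSAGE_META if c not in df.columns]
    if missing:
        raise SchemaError(f"dosage TSV missing columns {missing}")
    samples = [c for c in df.columns if c not in _DOSAGE_META]
    return GenotypeBlock(
        dosages=df[samples].to_numpy(dtype=float),
        variants=df[_DOSAGE_META].copy(),
        samples=samples,
    )


def write_phenotypes(table: PhenotypeTable, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"#state={table.state}\n#tg_scale={table.tg_scale}\n")
        table.df.to_csv(
            fh, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA",
            lineterminator="\n",
        )


def read_phenotypes(path) -> PhenotypeTable:
    state, tg_scale = "raw", "raw"
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            if key == "state":
                state = val
            elif key == "tg_scale":
                tg_scale = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    if "sample_id" not in df.columns:
        raise SchemaError("phenotype TSV missing sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    for col in ("age", "sex", *TRAITS, *PC_COLUMNS):
        if col in df.columns:
            df[col] = df[col].astype(float)
    return PhenotypeTable(df=df, state=state, tg_scale=tg_scale)


def write_truth(truth, path) -> None:
    truth.df.to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# results TSV (GEM-style per-trait summary statistics)
# ---------------------------------------------------------------------------


def write_results(rows: pd.DataFrame, path, header_meta: dict | None = None) -> None:
    """Write scan rows in the results TSV dialect.

    ``#``-prefixed header lines record configuration, seed and SE type;
    the column set is the fixed dialect plus any extra columns present
    (trait, significance flags).
    """
    cols = [c for c in RESULT_COLUMNS if c in rows.columns]
    extra = [c for c in rows.columns if c not in RESULT_COLUMNS]
    out = rows[cols + extra]
    with open(path, "w", newline="\n") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"#{k}={v}\n")
        out.to_csv(
            fh, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA",
            lineterminator="\n",
        )


def read_results(path, required=("SNPID", "CHR", "POS", "P_Int")) -> pd.DataFrame:
    """Read a results TSV back; raises :class:`SchemaError` naming the
    first missing required column."""
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise SchemaError("results file has no header line")
    df = pd.read_csv(_io.StringIO("".join(lines)), sep="\t", na_values=["NA"])
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"results file missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _leads_frame(leads_by_trait: dict) -> pd.DataFrame:
    recs = []
    for trait, leads in leads_by_trait.items():
        for lead in leads:
            rec = {"trait": trait}
            rec.update({k: lead.row[k] for k in lead.row.index if k in RESULT_COLUMNS})
            rec["n_members"] = len(lead.members)
            rec["members"] = ";".join(lead.members)
            rec["genes"] = ";".join(f"{g}({d})" for g, d in lead.genes)
            recs.append(rec)
    return pd.DataFrame(recs)


def run_pipeline(config: AnalysisConfig, out_dir) -> Path:
    """Execute the full pipeline and write every stage artifact.

    simulate (when ``config.simulate`` is set) -> preprocess -> scan (both
    models) -> threshold/flag -> clump (interaction and marginal leads) ->
    positional gene mapping -> look-up -> stratified estimation for
    interaction leads; plus a run manifest (version, seed, config hash)
    and a plain-text report. Identical config and seed give byte-identical
    outputs.
    """
    from .leads import LDSource, lookup_interactions, map_genes, read_bed
    from .phenoprep import preprocess, summarize_cohort
    from .scan import InteractionScan
    from .simulate import (
        MedicationModel,
        SimulationSpec,
        VariantSpec,
        simulate_cohort,
    )
    from .strata import genotype_frequencies, stratified_fit

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.seed is None:
        raise ValueError("a seed is mandatory for the pipeline")

    stage = "simulate"
    try:
        sim = dict(config.simulate)
        variants = [VariantSpec(**v) for v in sim.pop("variants", [])]
        med = MedicationModel(**sim.pop("medication", {}))
        ld_blocks = [tuple(b) for b in sim.pop("ld_blocks", [])]
        spec = SimulationSpec(
            variants=variants, medication=med, ld_blocks=ld_blocks,
            seed=config.seed, **sim,
        )
        geno, pheno_raw, truth = simulate_cohort(spec)
        write_vcf(geno, out / "genotypes.vcf")
        write_phenotypes(pheno_raw, out / "phenotypes_raw.tsv")
        write_truth(truth, out / "truth.tsv")

        stage = "preprocess"
        pheno = preprocess(pheno_raw, config.prep_config())
        write_phenotypes(pheno, out / "phenotypes_preprocessed.tsv")
        summary = summarize_cohort(pheno, config.age_bins)
        summary.table.to_csv(
            out / "cohort_summary.tsv", sep="\t", index=False, lineterminator="\n"
        )

        stage = "scan"
        scan_cfg = config.scan_config()
        results = InteractionScan(geno, pheno, config=scan_cfg).fit()
        header = {
            "agescan_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "se_type": config.se_type,
            "maf_min": config.maf_min,
            "per_trait_threshold": f"{results.threshold:g}",
        }
        for trait in results.traits:
            write_results(results.for_trait(trait), out / f"scan_{trait}.tsv", header)

        stage = "clump"
        # restrict LD to the analysed sample intersection, matching the scan
        ld = LDSource.from_genotypes(geno)
        int_leads = {
            t: results.clump(ld, t, kind="interaction", r2_max=config.clump_r2_max)
            for t in results.traits
        }
        marg_leads = {
            t: results.clump(ld, t, kind="marginal", r2_max=config.clump_r2_max)
            for t in results.traits
        }

        stage = "map_genes"
        genes = read_bed(config.genes_bed) if config.genes_bed else []
        if genes:
            for leads in (*int_leads.values(), *marg_leads.values()):
                map_genes(leads, genes, config.gene_max_dist)
        _leads_frame(int_leads).to_csv(
            out / "leads_interaction.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT, lineterminator="\n",
        )
        _leads_frame(marg_leads).to_csv(
            out / "leads_marginal.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT, lineterminator="\n",
        )

        stage = "lookup"
        lookup = lookup_interactions(marg_leads, results.table, config.lookup_alpha)
        lookup.to_csv(
            out / "lookup.tsv", sep="\t", index=False, float_format=_FLOAT_FMT,
            lineterminator="\n",
        )

        stage = "stratify"
        strata_rows, freq_frames = [], []
        pos_in_pheno = {s: i for i, s in enumerate(geno.samples)}
        order = [pos_in_pheno[s] for s in pheno.df["sample_id"]]
        for trait, leads in int_leads.items():
            for lead in leads:
                dos = geno.dosage_for(lead.id)[order]
                ests = stratified_fit(
                    pheno, dos, lead.id, trait, age_bins=config.age_bins
                )
                strata_rows.extend(asdict(e) for e in ests)
                freq_frames.append(
                    genotype_frequencies(
                        dos, pheno.df["age"].to_numpy(), config.age_bins, lead.id
                    )
                )
        pd.DataFrame(strata_rows).to_csv(
            out / "strata.tsv", sep="\t", index=False, float_format=_FLOAT_FMT,
            lineterminator="\n",
        )
        (pd.concat(freq_frames, ignore_index=True) if freq_frames else pd.DataFrame()).to_csv(
            out / "genotype_frequencies.tsv", sep="\t", index=False,
            lineterminator="\n",
        )
    except Exception as err:
        raise type(err)(f"[stage: {stage}] {err}") from err

    manifest = {
        "agescan_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "per_trait_threshold": results.threshold,
        "n_samples": int(pheno.n),
        "n_variants": int(geno.n_variants),
        "n_interaction_leads": {t: len(v) for t, v in int_leads.items()},
        "n_marginal_leads": {t: len(v) for t, v in marg_leads.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    lines = [
        f"agescan {__version__} pipeline report",
        f"seed: {config.seed}  config hash: {config.config_hash()}",
        f"cohort: {pheno.n} individuals, {geno.n_variants} variants",
        f"per-trait interaction threshold: {results.threshold:g}",
        "",
        "Interaction leads:",
    ]
    for trait, leads in int_leads.items():
        for lead in leads:
            genes_s = ", ".join(g for g, _ in lead.genes) or "-"
            lines.append(
                f"  {trait}: {lead.id} {lead.chrom}:{lead.pos} "
                f"beta_int={lead.row['Beta_GxAge']:.4g} "
                f"p_int={lead.row['P_Int']:.3g} genes: {genes_s}"
            )
    lines.append("")
    lines.append("Look-up hits (marginal leads with significant interaction):")
    hits = lookup[lookup["significant"]] if len(lookup) else lookup
    for _, r in hits.iterrows():
        lines.append(
            f"  {r['trait']}: {r['RSID']} beta_int={r['Beta_GxAge']:.4g} "
            f"p_int={r['P_Int']:.3g} threshold={r['threshold']:.3g}"
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return out
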