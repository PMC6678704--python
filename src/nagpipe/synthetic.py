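"""Synthetic NSCLC-like cohorts with planted ground truth.

The generator produces the joint data the downstream analysis assumes:
sparse binary gene-level alteration profiles with a planted protective
panel, right-censored survival whose hazard decreases with planted-gene
burden, group-shifted expression for signature genes, random protein
sequences, HLA-A genotypes, and planted strong-binder peptides for a chosen
set of immunogenic patients.  Every random draw comes from one
``numpy.random.default_rng`` (PCG64) stream seeded from the config, so an
identical config gives bit-identical output on any platform.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alterations import MAF_COLUMNS
from .neoantigen import HLA_GENE, apply_missense, enumerate_peptides

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# common HLA-A alleles sampled for synthetic genotypes (all supertyped by
# the shipped default table)
HLA_ALLELE_POOL = (
    "HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01", "HLA-A*11:01",
    "HLA-A*24:02", "HLA-A*26:01", "HLA-A*31:01", "HLA-A*68:01",
)

__all__ = ["SimulationConfig", "CohortBundle", "simulate_cohort",
           "write_bundle", "read_bundle", "bundles_equal"]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    The defaults emulate an early-stage NSCLC cohort with a strongly
    bimodal alteration burden: a latent patient group carries panel-gene
    alterations at a much higher rate, and each altered panel gene lowers
    the log hazard by ``beta_per_alteration`` (negative = protective).
    """

    n_patients: int = 300
    n_genes: int = 500
    n_panel_genes: int = 50
    alteration_rate_background: float = 0.05
    # probability an altered panel gene per patient; scalar, or a (low-group,
    # high-group) pair indexed by the latent patient group
    alteration_rate_panel: float | tuple[float, float] = (0.2, 0.7)
    # fraction of patients in the high-rate latent group; 0.75 aligns the
    # first-quartile burden cut with the latent mode boundary
    latent_high_fraction: float = 0.75
    beta_per_alteration: float = -0.05
    baseline_hazard: float = 0.35          # events / year
    weibull_shape: float = 1.0             # 1.0 = exponential
    censoring_rate: float = 0.05           # exponential censoring hazard / year
    followup_horizon: float = 5.0          # years
    n_signature_genes: int = 40
    signature_shift: float = 1.0           # asinh-scale mean difference
    noise_sd: float = 0.5                  # asinh-scale expression noise
    n_immunogenic_patients: int = 10
    protein_length_range: tuple[int, int] = (50, 200)
    seed: int = 0

    def panel_rates(self) -> tuple[float, float]:
        r = self.alteration_rate_panel
        if np.isscalar(r):
            return float(r), float(r)
        lo, hi = r
        return float(lo), float(hi)

    def validate(self) -> None:
        rates = (self.alteration_rate_background, *self.panel_rates())
        if any(not 0.0 <= p <= 1.0 for p in rates):
            raise ValueError("alteration rates must lie in [0, 1]")
        for name in ("n_patients", "n_genes", "n_panel_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_panel_genes > self.n_genes:
            raise ValueError("n_panel_genes cannot exceed n_genes")
        if self.n_signature_genes > self.n_genes - self.n_panel_genes:
            raise ValueError("not enough non-panel genes for the signature set")
        if self.baseline_hazard <= 0 or self.weibull_shape <= 0:
            raise ValueError("baseline_hazard and weibull_shape must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be nonnegative")
        if self.followup_horizon <= 0:
            raise ValueError("followup_horizon must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.protein_length_range
        if lo < 12 or hi < lo:
            raise ValueError("protein_length_range must be (lo, hi), lo >= 12")
        # unfittable designs: expected events < 2 per latent group
        # (exponential approximation at the group's expected burden)
        if not 0.0 < self.latent_high_fraction < 1.0:
            raise ValueError("latent_high_fraction must lie in (0, 1)")
        r_lo, r_hi = self.panel_rates()
        n_hi = int(self.n_patients * self.latent_high_fraction)
        for n_g, rate in ((self.n_patients - n_hi, r_lo), (n_hi, r_hi)):
            burden = self.n_panel_genes * rate
            h = self.baseline_hazard * np.exp(self.beta_per_alteration * burden)
            c = self.censoring_rate
            hz = self.followup_horizon
            p_event = h / (h + c) * (1.0 - np.exp(-(h + c) * hz)) if (h + c) > 0 else 0.0
            if n_g * p_event < 2.0:
                raise ValueError(
                    f"expected events in a latent group is {n_g * p_event:.2f} < 2; "
                    "the design is unfittable"
                )


@dataclass
class CohortBundle:
    """Joint synthetic output: all inputs the analysis consumes + truth."""

    variants: pd.DataFrame          # MAF-like
    lrr: pd.DataFrame               # gene x patient
    expression: pd.DataFrame        # gene x patient, RSEM-like nonnegative
    clinical: pd.DataFrame          # per-patient survival + covariates
    hla: pd.DataFrame               # sample_id-indexed allele_1/allele_2
    proteome: dict[str, str]        # gene -> amino-acid sequence
    truth: dict                     # planted panel, groups, binders, ...
    config: SimulationConfig

    def validate(self) -> None:
        for row in self.variants.itertuples(index=False):
            seq = self.proteome.get(str(row.gene))
            if seq is None:
                raise ValueError(f"variant gene {row.gene} missing from proteome")
            if not 1 <= int(row.protein_pos) <= len(seq):
                raise ValueError(f"variant position {row.protein_pos} outside "
                                 f"{row.gene} (length {len(seq)})")
        fu = self.clinical["followup_years"].to_numpy()
        if np.any(fu <= 0):
            raise ValueError("follow-up times must be strictly positive")
        if not np.isin(self.clinical["death"].to_numpy(), (0, 1)).all():
            raise ValueError("event flags must be binary")
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("expression must be nonnegative")


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Draw one cohort under the configured generative model.

    Alteration indicators are Bernoulli per gene x patient (panel genes at
    the latent-group rate); each altered pair is realized as a missense
    variant, a copy-number call beyond |LRR| = 0.5, or both.  Survival times
    are Weibull (default exponential) with per-patient log hazard
    ``beta_per_alteration x planted-gene burden``, independently censored.
    Signature-gene expression is mean-shifted between burden groups on the
    asinh scale.  Planted immunogenic patients receive one guaranteed-binder
    peptide and boosted gene/HLA-A expression.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_patients, config.n_genes

    patients = [f"P{i + 1:04d}" for i in range(n)]
    genes = [f"G{j + 1:04d}" for j in range(m)]
    panel_genes = sorted(rng.choice(genes, size=config.n_panel_genes, replace=False))
    non_panel = [g for g in genes if g not in set(panel_genes)]
    signature_genes = sorted(rng.choice(non_panel, size=config.n_signature_genes,
                                        replace=False))

    # --- proteome -----------------------------------------------------------
    lo, hi = config.protein_length_range
    lengths = rng.integers(lo, hi + 1, size=m)
    aa = np.array(list(AMINO_ACIDS))
    proteome = {g: "".join(rng.choice(aa, size=L)) for g, L in zip(genes, lengths)}

    # --- alteration indicator -----------------------------------------------
    latent_high = rng.random(n) < config.latent_high_fraction
    r_lo, r_hi = config.panel_rates()
    rate = np.full((n, m), config.alteration_rate_background)
    panel_idx = [genes.index(g) for g in panel_genes]
    rate[:, panel_idx] = np.where(latent_high[:, None], r_hi, r_lo)
    altered = rng.random((n, m)) < rate

    # --- realize alterations as variants and/or copy number ------------------
    # mode: 0 = mutation, 1 = CNA, 2 = both
    mode = rng.choice(3, size=(n, m), p=(0.5, 0.3, 0.2))
    lrr_vals = rng.normal(0.0, 0.15, size=(m, n)).clip(-0.45, 0.45)
    var_rows = []
    for pi, gi in zip(*np.nonzero(altered)):
        g = genes[gi]
        if mode[pi, gi] in (0, 2):
            seq = proteome[g]
            pos = int(rng.integers(1, len(seq) + 1))
            ref = seq[pos - 1]
            alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref]))
            vaf = float(0.05 + 0.9 * rng.beta(2.0, 2.0))
            var_rows.append((patients[pi], g, pos, ref, alt, vaf))
        if mode[pi, gi] in (1, 2):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lrr_vals[gi, pi] = sign * rng.uniform(0.55, 2.0)
    variants = pd.DataFrame(var_rows, columns=MAF_COLUMNS)
    lrr = pd.DataFrame(lrr_vals, index=pd.Index(genes, name="gene"),
                       columns=patients)

    # --- survival -------------------------------------------------------------
    burden = altered[:, panel_idx].sum(axis=1)
    lp = config.beta_per_alteration * burden
    hazard = config.baseline_hazard * np.exp(lp)
    u = rng.random(n)
    t_event = (-np.log(u) / hazard) ** (1.0 / config.weibull_shape)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    limit = np.minimum(t_cens, config.followup_horizon)
    obs = np.minimum(t_event, limit)
    event = (t_event <= limit).astype(int)
    obs = np.maximum(obs, 1e-6)  # guard against numerically zero times

    # latent NAG group for the expression shift: burden quartile dichotomy
    q1 = np.quantile(burden, 0.25)
    nag_high = burden > q1

    # --- clinical covariates (independent of burden by default) ---------------
    relapse_draw = rng.random(n)
    relapse = ((event == 1) & (relapse_draw < 0.3)).astype(int)
    relapse_years = np.where(relapse == 1, obs * rng.uniform(0.4, 1.0, size=n), np.nan)
    clinical = pd.DataFrame({
        "sample_id": patients,
        "followup_years": obs,
        "death": event,
        "relapse": relapse,
        "relapse_years": relapse_years,
        "age": np.clip(np.round(rng.normal(66, 9, size=n)), 40, 90).astype(int),
        "sex": rng.choice(["M", "F"], size=n),
        "smoking": rng.choice(["smoker", "never"], size=n, p=(0.7, 0.3)),
        "histology": rng.choice(["adeno", "squamous"], size=n, p=(0.55, 0.45)),
        "stage": rng.choice(["I", "II"], size=n, p=(0.6, 0.4)),
    }).set_index("sample_id")

    # --- expression ------------------------------------------------------------
    expr_genes = genes + [HLA_GENE]
    mu = rng.uniform(1.0, 4.0, size=len(expr_genes))
    y = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(len(expr_genes), n))
    sig_idx = [expr_genes.index(g) for g in signature_genes]
    y[np.ix_(sig_idx, np.where(nag_high)[0])] += config.signature_shift
    expression = pd.DataFrame(np.sinh(y).clip(min=0.0),
                              index=pd.Index(expr_genes, name="gene"),
                              columns=patients)

    # --- HLA genotypes ----------------------------------------------------------
    alleles = rng.choice(HLA_ALLELE_POOL, size=(n, 2))
    hla = pd.DataFrame({"sample_id": patients, "allele_1": alleles[:, 0],
                        "allele_2": alleles[:, 1]}).set_index("sample_id")

    # --- plant immunogenic patients ---------------------------------------------
    has_variant = variants["sample_id"].unique() if len(variants) else []
    candidates = [p for p in patients if p in set(has_variant)]
    if len(candidates) < config.n_immunogenic_patients:
        raise ValueError(
            f"only {len(candidates)} patients carry variants; cannot plant "
            f"{config.n_immunogenic_patients} immunogenic patients"
        )
    chosen = sorted(rng.choice(candidates, size=config.n_immunogenic_patients,
                               replace=False))
    planted_binders: list[tuple[str, str]] = []
    for p in chosen:
        v = variants[variants["sample_id"] == p].iloc[0]
        mutated = apply_missense(proteome[v["gene"]], int(v["protein_pos"]),
                                 v["ref_aa"], v["alt_aa"], gene=v["gene"])
        peps = enumerate_peptides(mutated, int(v["protein_pos"]), gene=v["gene"])
        pep = peps[0].peptide
        for al in {hla.loc[p, "allele_1"], hla.loc[p, "allele_2"]}:
            planted_binders.append((pep, str(al)))
        # force both expression conditions above any possible median
        for gname in (v["gene"], HLA_GENE):
            expression.loc[gname, p] = float(expression.loc[gname].max()) * 1.5 + 1.0

    truth = {
        "panel_genes": list(panel_genes),
        "signature_genes": list(signature_genes),
        "latent_high_rate_group": [patients[i] for i in np.where(latent_high)[0]],
        "burden": {p: int(b) for p, b in zip(patients, burden)},
        "nag_high_group": [patients[i] for i in np.where(nag_high)[0]],
        "immunogenic_patients": list(chosen),
        "planted_binders": planted_binders,
    }
    bundle = CohortBundle(variants=variants, lrr=lrr, expression=expression,
                          clinical=clinical, hla=hla, proteome=proteome,
                          truth=truth, config=config)
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # lossless float64 round trip


def write_bundle(bundle: CohortBundle, directory) -> dict[str, Path]:
    """Write all bundle components as plain-text files; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": directory / "variants.maf.tsv",
        "lrr": directory / "lrr.tsv",
        "expression": directory / "expression.tsv",
        "clinical": directory / "clinical.tsv",
        "hla": directory / "hla.tsv",
        "proteome": directory / "proteome.fasta",
        "truth": directory / "truth.json",
        "config": directory / "config.yaml",
    }
    bundle.variants.to_csv(paths["variants"], sep="\t", index=False,
                           float_format=_FLOAT_FMT)
    bundle.lrr.to_csv(paths["lrr"], sep="\t", float_format=_FLOAT_FMT)
    bundle.expression.to_csv(paths["expression"], sep="\t", float_format=_FLOAT_FMT)
    bundle.clinical.to_csv(paths["clinical"], sep="\t", float_format=_FLOAT_FMT)
    bundle.hla.to_csv(paths["hla"], sep="\t")
    records = [SeqRecord(Seq(seq), id=g, description="")
               for g, seq in bundle.proteome.items()]
    SeqIO.write(records, paths["proteome"], "fasta")
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataclasses.asdict(bundle.config), fh, sort_keys=True)
    return paths


def read_bundle(directory) -> CohortBundle:
    """Read back a bundle written by :func:`write_bundle`."""
    directory = Path(directory)
    # float_precision='round_trip': the default C parser is not bit-exact,
    # which would break the written %.17g <-> float64 loss-free contract
    variants = pd.read_csv(directory / "variants.maf.tsv", sep="\t",
                           dtype={"sample_id": str, "gene": str,
                                  "ref_aa": str, "alt_aa": str},
                           float_precision="round_trip")
    if variants.empty:
        variants = pd.DataFrame(columns=MAF_COLUMNS)
    lrr = pd.read_csv(directory / "lrr.tsv", sep="\t", index_col=0,
                      float_precision="round_trip")
    expression = pd.read_csv(directory / "expression.tsv", sep="\t", index_col=0,
                             float_precision="round_trip")
    clinical = pd.read_csv(directory / "clinical.tsv", sep="\t", index_col=0,
                           dtype={"sample_id": str},
                           float_precision="round_trip")
    hla = pd.read_csv(directory / "hla.tsv", sep="\t", index_col=0,
                      dtype={"sample_id": str})
    proteome = {rec.id: str(rec.seq)
                for rec in SeqIO.parse(directory / "proteome.fasta", "fasta")}
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    truth["planted_binders"] = [tuple(x) for x in truth.get("planted_binders", [])]
    with open(directory / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    for key in ("alteration_rate_panel", "protein_length_range"):
        if isinstance(raw.get(key), list):
            raw[key] = tuple(raw[key])
    config = SimulationConfig(**raw)
    return CohortBundle(variants=variants, lrr=lrr, expression=expression,
                        clinical=clinical, hla=hla, proteome=proteome,
                        truth=truth, config=config)


def bundles_equal(a: CohortBundle, b: CohortBundle) -> bool:
    """Exact equality of every component (float64-lossless I/O)."""
    try:
        pd.testing.assert_frame_equal(a.variants.reset_index(drop=True),
                                      b.variants.reset_index(drop=True),
                                      check_dtype=False, check_exact=True)
        pd.testing.assert_frame_equal(a.lrr, b.lrr, check_exact=True)
        pd.testing.assert_frame_equal(a.expression, b.expression, check_exact=True)
        pd.testing.assert_frame_equal(a.clinical, b.clinical, check_dtype=False,
                                      check_exact=True)
        pd.testing.assert_frame_equal(a.hla, b.hla)
    except AssertionError:
        return False
    return (a.proteome == b.proteome and a.truth == b.truth
            and dataclasses.asdict(a.config) == dataclasses.asdict(b.config))
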