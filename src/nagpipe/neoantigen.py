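"""Mutant peptide enumeration and HLA-A immunogenicity classification.

Each missense variant is applied to its protein; every 8-11mer window
covering the altered residue is a candidate MHC class I ligand.  A peptide
is *antigenic* when its predicted IC50 is below 500 nM against both of the
patient's HLA-A alleles, and *immunogenic* when additionally the source
gene and the patient's HLA-A gene are expressed above the cohort medians
(all inequalities strict).  A patient is immunogenic with >= 1 immunogenic
peptide.  Affinity prediction is a pluggable backend: a precomputed table
for real predictor output, or a deterministic surrogate with planted strong
binders for self-contained analyses.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

AFFINITY_THRESHOLD_NM = 500.0
PEPTIDE_LENGTHS = (8, 9, 10, 11)
HLA_GENE = "HLA-A"

_ALLELE_RE = re.compile(r"^HLA-A\*\d{2}:\d{2,3}$")

__all__ = [
    "MutantPeptide",
    "ImmunogenicityCall",
    "apply_missense",
    "enumerate_peptides",
    "window_count",
    "load_supertype_table",
    "supertype_allele",
    "SurrogateAffinityBackend",
    "TableAffinityBackend",
    "predict_affinity",
    "call_antigenic",
    "call_immunogenic",
    "classify_patient",
    "classify_cohort",
    "three_group_stratification",
    "compare_vaf",
]


@dataclass(frozen=True)
class MutantPeptide:
    """An 8-11mer containing the altered residue.

    ``mutated_offset`` is 0-based within the peptide; ``protein_pos`` is the
    1-based residue index in the full protein.
    """

    gene: str
    peptide: str
    mutated_offset: int
    protein_pos: int

    def __post_init__(self) -> None:
        if not 8 <= len(self.peptide) <= 11:
            raise ValueError(f"peptide length {len(self.peptide)} outside 8-11")
        if not 0 <= self.mutated_offset < len(self.peptide):
            raise ValueError("mutated_offset outside peptide")


@dataclass
class ImmunogenicityCall:
    patient: str
    antigenic_count: int
    immunogenic_count: int

    def __post_init__(self) -> None:
        if self.immunogenic_count > self.antigenic_count:
            raise ValueError("immunogenic count cannot exceed antigenic count")

    @property
    def is_immunogenic(self) -> bool:
        return self.immunogenic_count >= 1


# ---------------------------------------------------------------------------
# peptide enumeration
# ---------------------------------------------------------------------------

def apply_missense(protein_seq: str, protein_pos: int, ref_aa: str, alt_aa: str,
                   gene: str = "?") -> str:
    """Substitute one residue (1-based position); the reference must match."""
    if not 1 <= protein_pos <= len(protein_seq):
        raise ValueError(
            f"{gene}: position {protein_pos} outside protein of length {len(protein_seq)}"
        )
    found = protein_seq[protein_pos - 1]
    if found != ref_aa:
        raise ValueError(
            f"{gene} p.{protein_pos}: reference residue mismatch "
            f"(expected {ref_aa}, protein has {found}); wrong isoform?"
        )
    return protein_seq[: protein_pos - 1] + alt_aa + protein_seq[protein_pos:]


def enumerate_peptides(
    mutated_seq: str,
    protein_pos: int,
    gene: str = "?",
    lengths=PEPTIDE_LENGTHS,
) -> list[MutantPeptide]:
    """All windows of the given lengths that contain the altered residue.

    Windows must lie fully inside the protein; identical peptide strings
    arising from different windows are deduplicated (first occurrence kept).
    """
    P = len(mutated_seq)
    out: dict[str, MutantPeptide] = {}
    for L in lengths:
        start_min = max(1, protein_pos - L + 1)
        start_max = min(protein_pos, P - L + 1)
        for start in range(start_min, start_max + 1):  # 1-based window start
            pep = mutated_seq[start - 1: start - 1 + L]
            if pep not in out:
                out[pep] = MutantPeptide(
                    gene=gene, peptide=pep,
                    mutated_offset=protein_pos - start, protein_pos=protein_pos,
                )
    return list(out.values())


def window_count(protein_length: int, protein_pos: int,
                 lengths=PEPTIDE_LENGTHS) -> int:
    """Closed-form number of windows covering the position (before dedup)."""
    total = 0
    for L in lengths:
        lo = max(1, protein_pos - L + 1)
        hi = min(protein_pos, protein_length - L + 1)
        total += max(0, hi - lo + 1)
    return total


# ---------------------------------------------------------------------------
# HLA supertyping
# ---------------------------------------------------------------------------

def load_supertype_table(path=None) -> dict[str, str]:
    """Allele -> supertype mapping; default table shipped with the package."""
    if path is None:
        with resources.files("nagpipe.data").joinpath("hla_supertypes.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["allele"], df["supertype"]))


def supertype_allele(allele: str, mapping_table: dict[str, str] | None = None) -> str:
    """Supertype of a 4-digit HLA-A allele; 'unclassified' when unmapped."""
    if not _ALLELE_RE.match(allele):
        raise ValueError(f"malformed HLA-A allele string: {allele!r} "
                         "(expected e.g. 'HLA-A*02:01')")
    if mapping_table is None:
        mapping_table = load_supertype_table()
    st = mapping_table.get(allele)
    if st is None:
        logger.warning("allele %s not in supertype table; marked unclassified", allele)
        return "unclassified"
    return st


# ---------------------------------------------------------------------------
# affinity backends
# ---------------------------------------------------------------------------

class SurrogateAffinityBackend:
    """Deterministic pseudo-affinity model (synthetic stand-in for an
    external MHC binding predictor).

    The IC50 of a (peptide, allele) pair is a pure hash-derived function:
    pairs on the planted-binder list score uniformly in [20, 420) nM (strong
    binders), all others in [600, 50000) nM (non-binders).  Identical inputs
    give identical values on every platform.
    """

    def __init__(self, planted_binders=()):
        self.planted_binders = {(p, a) for p, a in planted_binders}

    @staticmethod
    def _unit(peptide: str, allele: str) -> float:
        h = hashlib.blake2b(f"{peptide}|{allele}".encode(), digest_size=8).digest()
        return int.from_bytes(h, "big") / 2**64

    def ic50(self, peptide: str, allele: str) -> float:
        u = self._unit(peptide, allele)
        if (peptide, allele) in self.planted_binders:
            return 20.0 + 400.0 * u
        return 600.0 + 49400.0 * u


class TableAffinityBackend:
    """Precomputed predictions from a TSV with columns peptide, allele, ic50_nm."""

    def __init__(self, table: pd.DataFrame):
        required = {"peptide", "allele", "ic50_nm"}
        if not required.issubset(table.columns):
            raise ValueError(f"affinity table needs columns {sorted(required)}")
        if (table["ic50_nm"] <= 0).any():
            raise ValueError("ic50 values must be positive")
        self._map = {(p, a): float(v) for p, a, v in
                     zip(table["peptide"], table["allele"], table["ic50_nm"])}

    @classmethod
    def from_tsv(cls, path) -> "TableAffinityBackend":
        return cls(pd.read_csv(path, sep="\t"))

    def ic50(self, peptide: str, allele: str) -> float:
        try:
            return self._map[(peptide, allele)]
        except KeyError:
            raise KeyError(f"no affinity for pair ({peptide}, {allele})") from None


def predict_affinity(peptides, alleles, backend) -> pd.DataFrame:
    """One IC50 (nM) per peptide x allele; errors list all missing pairs."""
    pep_strings = [p.peptide if isinstance(p, MutantPeptide) else str(p)
                   for p in peptides]
    alleles = list(dict.fromkeys(alleles))
    rows, missing = [], []
    for pep in dict.fromkeys(pep_strings):
        for allele in alleles:
            try:
                rows.append({"peptide": pep, "allele": allele,
                             "ic50_nm": backend.ic50(pep, allele)})
            except KeyError:
                missing.append((pep, allele))
    if missing:
        raise KeyError(f"affinity backend missing {len(missing)} pairs: {missing[:5]}")
    return pd.DataFrame(rows, columns=["peptide", "allele", "ic50_nm"])


# ---------------------------------------------------------------------------
# immunogenicity conditions
# ---------------------------------------------------------------------------

def call_antigenic(ic50_allele1: float, ic50_allele2: float,
                   threshold: float = AFFINITY_THRESHOLD_NM) -> bool:
    """Strong binder against BOTH patient alleles (strict < threshold)."""
    return ic50_allele1 < threshold and ic50_allele2 < threshold


def call_immunogenic(antigenic: bool, gene_expression: float, gene_median: float,
                     hla_expression: float, hla_median: float) -> bool:
    """Antigenic AND gene expressed above cohort median AND HLA-A above median.

    Both expression comparisons are strict.
    """
    return bool(antigenic
                and gene_expression > gene_median
                and hla_expression > hla_median)


def classify_patient(patient: str, peptide_calls: pd.DataFrame) -> ImmunogenicityCall:
    """Aggregate per-peptide calls; immunogenic iff >= 1 immunogenic peptide."""
    return ImmunogenicityCall(
        patient=patient,
        antigenic_count=int(peptide_calls["antigenic"].sum()),
        immunogenic_count=int(peptide_calls["immunogenic"].sum()),
    )


def classify_cohort(
    variants: pd.DataFrame,
    proteome: dict[str, str],
    hla: pd.DataFrame,
    expression,
    backend,
    affinity_threshold: float = AFFINITY_THRESHOLD_NM,
    panel=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full peptide pipeline for a cohort.

    Parameters
    ----------
    variants
        MAF-like table (sample_id, gene, protein_pos, ref_aa, alt_aa, vaf).
    proteome
        gene -> amino-acid sequence.
    hla
        table indexed by sample_id with columns allele_1, allele_2.
    expression
        gene x sample matrix on the raw (linear) scale; must contain an
        'HLA-A' row for the receptor-expression condition.
    panel
        optional gene set restricting which variants are considered.

    Returns (per-peptide calls, per-patient classification) tables.
    """
    from .signature import ExpressionMatrix

    if isinstance(expression, ExpressionMatrix):
        if expression.transformed:
            raise ValueError("immunogenicity medians use the raw expression scale")
        expression = expression.values
    if HLA_GENE not in expression.index:
        raise ValueError(f"expression matrix lacks an {HLA_GENE} row")
    gene_medians = expression.median(axis=1)
    hla_median = float(gene_medians[HLA_GENE])

    sup_table = load_supertype_table()
    panel_set = {g for g in panel} if panel is not None else None

    pep_rows = []
    for row in variants.itertuples(index=False):
        gene = str(row.gene)
        if panel_set is not None and gene not in panel_set:
            continue
        patient = str(row.sample_id)
        if patient not in hla.index:
            logger.warning("no HLA genotype for %s; variants skipped", patient)
            continue
        seq = proteome.get(gene)
        if seq is None:
            logger.warning("gene %s missing from proteome; variant skipped", gene)
            continue
        mutated = apply_missense(seq, int(row.protein_pos), row.ref_aa, row.alt_aa,
                                 gene=gene)
        a1, a2 = str(hla.loc[patient, "allele_1"]), str(hla.loc[patient, "allele_2"])
        # homozygous patients need a single affinity evaluation
        distinct = [a1] if a1 == a2 else [a1, a2]
        if gene in expression.index:
            gene_expr = float(expression.loc[gene, patient]) \
                if patient in expression.columns else np.nan
            gene_med = float(gene_medians[gene])
        else:
            logger.warning("gene %s absent from expression matrix; peptides "
                           "non-immunogenic", gene)
            gene_expr, gene_med = np.nan, np.nan
        hla_expr = float(expression.loc[HLA_GENE, patient]) \
            if patient in expression.columns else np.nan

        for pep in enumerate_peptides(mutated, int(row.protein_pos), gene=gene):
            ic50s = {al: backend.ic50(pep.peptide, al) for al in distinct}
            antigenic = call_antigenic(ic50s[a1], ic50s[a2], affinity_threshold)
            immunogenic = (
                call_immunogenic(antigenic, gene_expr, gene_med, hla_expr, hla_median)
                if np.isfinite(gene_expr) and np.isfinite(hla_expr) else False
            )
            pep_rows.append({
                "sample_id": patient, "gene": gene, "peptide": pep.peptide,
                "protein_pos": pep.protein_pos, "vaf": float(row.vaf),
                "allele_1": a1, "allele_2": a2,
                "supertype_1": supertype_allele(a1, sup_table),
                "supertype_2": supertype_allele(a2, sup_table),
                "ic50_allele_1": ic50s[a1], "ic50_allele_2": ic50s[a2],
                "antigenic": antigenic, "immunogenic": immunogenic,
            })

    peptide_calls = pd.DataFrame(pep_rows, columns=[
        "sample_id", "gene", "peptide", "protein_pos", "vaf", "allele_1",
        "allele_2", "supertype_1", "supertype_2", "ic50_allele_1",
        "ic50_allele_2", "antigenic", "immunogenic"])
    # dedup identical peptides per (patient, gene, peptide)
    if len(peptide_calls):
        peptide_calls = peptide_calls.drop_duplicates(
            subset=["sample_id", "gene", "peptide"]).reset_index(drop=True)

    patients = [str(s) for s in hla.index]
    calls = []
    for patient in patients:
        sub = peptide_calls[peptide_calls["sample_id"] == patient] if len(peptide_calls) \
            else pd.DataFrame({"antigenic": [], "immunogenic": []})
        c = classify_patient(patient, sub)
        calls.append({"sample_id": patient, "antigenic_peptides": c.antigenic_count,
                      "immunogenic_peptides": c.immunogenic_count,
                      "is_immunogenic": c.is_immunogenic})
    patient_calls = pd.DataFrame(calls).set_index("sample_id")
    return peptide_calls, patient_calls


def three_group_stratification(nag_labels: pd.Series,
                               immunogenic: pd.Series) -> pd.Series:
    """Stratify patients into low_nag / high_nag_nonimmunogenic /
    high_nag_immunogenic.

    An immunogenic low-burden patient (a combination absent from the
    motivating cohort) is assigned low_nag with a warning.
    """
    nag_labels = pd.Series(nag_labels)
    immunogenic = pd.Series(immunogenic).reindex(nag_labels.index)
    odd = (nag_labels == "low") & immunogenic.astype(bool)
    if odd.any():
        logger.warning("%d immunogenic low-burden patients assigned to low_nag",
                       int(odd.sum()))
    out = np.where(
        nag_labels == "low", "low_nag",
        np.where(immunogenic.astype(bool), "high_nag_immunogenic",
                 "high_nag_nonimmunogenic"),
    )
    return pd.Series(out, index=nag_labels.index, name="strat_group")


def compare_vaf(immunogenic_vafs, other_vafs) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum on variant allele fractions.

    Tests whether immunogenic mutations are shifted (e.g. subclonal, lower
    VAF) relative to the remaining mutations.  Returns (U statistic for the
    immunogenic group, p) using the normal approximation with tie correction.
    """
    x = np.asarray(immunogenic_vafs, dtype=float)
    y = np.asarray(other_vafs, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both VAF groups must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)
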