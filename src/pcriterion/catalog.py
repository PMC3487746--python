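"""Case-control variant catalogs: IO, classification, arm-level rollups.

A catalog is a table of meta-analytic case-control allele frequencies, one
row per variant, as curated in candidate-gene databases (SZGene-style):
gene symbol, variant id, cytogenetic location, the two alleles with the
risk allele marked, and the risk-allele frequencies in cases (``mA``) and
controls (``mU``).  The per-variant statistic is ``d = mA - mU``, compared
strictly against the persistence threshold ``nu``:

* ``MEETS``        0 < d < nu   — compatible with a susceptibility allele,
* ``EXCEEDS``      d >= nu      — too large to persist as a risk allele;
                                  under mutation-selection balance the
                                  allele must be protective,
* ``NONPOSITIVE``  d <= 0       — no positive association.

Rollups go variant -> gene (a gene "meets" if any of its variants does)
-> chromosome arm (an arm meets if any resident gene does).  The headline
count of "protective loci outside" is the number of non-meeting genes that
have at least one EXCEEDS variant and sit on arms carrying no meeting gene.

``d`` is always computed from the stored frequencies, never read from a
catalog's pre-rounded ``printed_d`` column: the interesting variants sit
within rounding distance of ``nu``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import CriterionThreshold

__all__ = [
    "VariantRecord",
    "CytoBand",
    "VariantClass",
    "CatalogSummary",
    "CatalogSchemaError",
    "parse_cytoband",
    "allele_diff",
    "classify_variant",
    "odds_ratio_from_freqs",
    "summarize_catalog",
    "read_catalog",
    "write_catalog",
    "load_reference_catalog",
]

_VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X"])

_CYTOBAND_RE = re.compile(r"^(\d{1,2}|X)([pq])(.*)$")


class CatalogSchemaError(ValueError):
    """A catalog file is missing required columns or has malformed rows."""


@dataclass(frozen=True)
class CytoBand:
    """A cytogenetic location split into chromosome, arm and sub-band."""

    chromosome: str
    arm: str
    sub_band: str = ""

    def __post_init__(self) -> None:
        if self.chromosome not in _VALID_CHROMS:
            raise ValueError(f"invalid chromosome label {self.chromosome!r}")
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")

    @property
    def arm_label(self) -> str:
        """Chromosome + arm, e.g. ``1p`` — the unit of regional co-location."""
        return f"{self.chromosome}{self.arm}"

    def __str__(self) -> str:
        return f"{self.chromosome}{self.arm}{self.sub_band}"


def parse_cytoband(location: str) -> CytoBand:
    """Split a band string like ``"1p36.22"`` at the first arm letter.

    The sub-band is preserved verbatim (it may be empty, as in ``"2q13"``'s
    sibling ``"8p12"`` — any trailing text after p/q is kept as printed).
    """
    if not location or not isinstance(location, str):
        raise ValueError("location must be a non-empty string")
    m = _CYTOBAND_RE.match(location.strip())
    if m is None:
        raise ValueError(f"cannot parse cytogenetic location {location!r}")
    chrom, arm, sub = m.groups()
    return CytoBand(chromosome=chrom, arm=arm, sub_band=sub)


class VariantClass(enum.Enum):
    """Exhaustive, mutually exclusive classes of a finite d against nu."""

    MEETS = "MEETS"
    EXCEEDS = "EXCEEDS"
    NONPOSITIVE = "NONPOSITIVE"


@dataclass(frozen=True)
class VariantRecord:
    """One catalog row, risk-allele oriented.

    ``freq_cases``/``freq_controls`` are the frequencies of the marked risk
    allele as printed in the source table, even where that allele is the
    major allele; orientation is never flipped.
    """

    gene: str
    variant_id: str
    location: str
    allele_minor: str
    allele_major: str
    risk_allele: str
    freq_cases: float
    freq_controls: float
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    reported_or: Optional[float] = None
    printed_d: Optional[float] = None

    def __post_init__(self) -> None:
        for name, f in (("freq_cases", self.freq_cases), ("freq_controls", self.freq_controls)):
            if f is None or not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.variant_id}: {name} must lie in [0, 1], got {f}")
        if self.risk_allele not in (self.allele_minor, self.allele_major):
            raise ValueError(
                f"{self.variant_id}: risk allele {self.risk_allele!r} is neither "
                f"{self.allele_minor!r} nor {self.allele_major!r}"
            )

    @property
    def cytoband(self) -> CytoBand:
        return parse_cytoband(self.location)


def allele_diff(record: VariantRecord) -> float:
    """Case-control risk-allele frequency difference d = mA - mU."""
    return record.freq_cases - record.freq_controls


def classify_variant(d: float, nu: CriterionThreshold | float) -> VariantClass:
    """Classify ``d`` against the unrounded threshold, strict inequalities.

    A tie ``d == nu`` classifies EXCEEDS: the criterion is ``0 < d < nu``.
    """
    nu_value = nu.nu if isinstance(nu, CriterionThreshold) else float(nu)
    if nu_value <= 0:
        raise ValueError(f"nu must be positive, got {nu_value}")
    if d <= 0:
        return VariantClass.NONPOSITIVE
    if d < nu_value:
        return VariantClass.MEETS
    return VariantClass.EXCEEDS


def odds_ratio_from_freqs(mA: float, mU: float) -> float:
    """Allelic odds ratio (mA/(1-mA)) / (mU/(1-mU)).

    Diagnostic only: published catalog ORs are meta-analytic summaries and
    are generally not reproducible from the pooled frequencies.
    """
    if not (0.0 < mA < 1.0 and 0.0 < mU < 1.0):
        raise ValueError("frequencies must lie strictly inside (0, 1)")
    return (mA / (1.0 - mA)) / (mU / (1.0 - mU))


@dataclass
class CatalogSummary:
    """Classified catalog with gene- and arm-level rollups.

    Attributes
    ----------
    variants
        One row per variant: gene, variant_id, location, arm, d, class.
    genes
        One row per gene: arm, n_variants, n_meets, n_exceeds, gene_meets.
    arms
        One row per arm: n_genes, arm_meets.
    n_meeting_variants, n_meeting_loci
        Counts of MEETS variants and of genes with >= 1 MEETS variant.
    n_protective_loci_outside
        Non-meeting genes with >= 1 EXCEEDS variant on arms carrying no
        meeting gene.
    outside_arms
        Mapping arm -> sorted genes contributing to the outside count.
    """

    nu: CriterionThreshold
    variants: pd.DataFrame
    genes: pd.DataFrame
    arms: pd.DataFrame
    n_meeting_variants: int
    n_meeting_loci: int
    n_protective_loci_outside: int
    outside_arms: dict[str, list[str]] = field(default_factory=dict)

    @property
    def meeting_genes(self) -> list[str]:
        return sorted(self.genes.index[self.genes["gene_meets"]])

    @property
    def meeting_arms(self) -> list[str]:
        return sorted(self.arms.index[self.arms["arm_meets"]])

    def report(self) -> str:
        """Human-readable multi-line summary."""
        lines = [
            f"threshold nu = {self.nu.nu:.6g} "
            f"(p={self.nu.params_used.prevalence:.4g}, "
            f"s={self.nu.params_used.selection_coefficient:.4g}, "
            f"mu={self.nu.mu_used:.4g})",
            f"variants meeting 0 < d < nu : {self.n_meeting_variants}",
            f"loci (genes) meeting        : {self.n_meeting_loci}",
            f"protective loci outside     : {self.n_protective_loci_outside}",
            f"meeting arms: {', '.join(self.meeting_arms) or '(none)'}",
        ]
        for arm in sorted(self.outside_arms):
            lines.append(f"  outside arm {arm}: {', '.join(self.outside_arms[arm])}")
        return "\n".join(lines)


def summarize_catalog(
    records: Sequence[VariantRecord], nu: CriterionThreshold
) -> CatalogSummary:
    """Classify every variant and aggregate to genes and chromosome arms.

    Raises
    ------
    ValueError
        With row context if a location fails to parse, or if a gene symbol
        appears on more than one arm (each gene must map to a single arm).
    """
    rows = []
    for i, rec in enumerate(records):
        try:
            band = rec.cytoband
        except ValueError as exc:
            raise ValueError(f"row {i} ({rec.gene}/{rec.variant_id}): {exc}") from exc
        d = allele_diff(rec)
        rows.append(
            {
                "gene": rec.gene,
                "variant_id": rec.variant_id,
                "location": rec.location,
                "arm": band.arm_label,
                "d": d,
                "variant_class": classify_variant(d, nu).value,
            }
        )
    variants = pd.DataFrame(
        rows, columns=["gene", "variant_id", "location", "arm", "d", "variant_class"]
    )

    if variants.empty:
        genes = pd.DataFrame(
            columns=["arm", "n_variants", "n_meets", "n_exceeds", "gene_meets"]
        )
        genes.index.name = "gene"
        arms = pd.DataFrame(columns=["n_genes", "arm_meets"])
        arms.index.name = "arm"
        return CatalogSummary(
            nu=nu, variants=variants, genes=genes, arms=arms,
            n_meeting_variants=0, n_meeting_loci=0, n_protective_loci_outside=0,
        )

    multi_arm = variants.groupby("gene")["arm"].nunique()
    offenders = multi_arm[multi_arm > 1]
    if not offenders.empty:
        raise ValueError(
            f"gene(s) mapped to multiple arms: {', '.join(offenders.index)}"
        )

    genes = (
        variants.assign(
            is_meet=variants["variant_class"] == VariantClass.MEETS.value,
            is_exceed=variants["variant_class"] == VariantClass.EXCEEDS.value,
        )
        .groupby("gene")
        .agg(
            arm=("arm", "first"),
            n_variants=("variant_id", "size"),
            n_meets=("is_meet", "sum"),
            n_exceeds=("is_exceed", "sum"),
        )
        .sort_index()
    )
    genes["gene_meets"] = genes["n_meets"] > 0

    arms = (
        genes.groupby("arm")
        .agg(n_genes=("gene_meets", "size"), arm_meets=("gene_meets", "any"))
        .sort_index()
    )

    outside_mask = (
        ~genes["gene_meets"]
        & (genes["n_exceeds"] > 0)
        & ~genes["arm"].map(arms["arm_meets"])
    )
    outside = genes[outside_mask]
    outside_arms = {
        arm: sorted(sub.index) for arm, sub in outside.groupby("arm")
    }

    return CatalogSummary(
        nu=nu,
        variants=variants,
        genes=genes,
        arms=arms,
        n_meeting_variants=int((variants["variant_class"] == "MEETS").sum()),
        n_meeting_loci=int(genes["gene_meets"].sum()),
        n_protective_loci_outside=int(outside_mask.sum()),
        outside_arms=outside_arms,
    )


_REQUIRED_COLUMNS = [
    "gene", "variant_id", "location", "allele_minor", "allele_major",
    "risk_allele", "freq_cases", "freq_controls",
]
_OPTIONAL_COLUMNS = ["n_cases", "n_controls", "reported_or", "printed_d"]
_ALL_COLUMNS = _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS


def read_catalog(path: str | Path, dialect: str = "csv") -> list[VariantRecord]:
    """Read a delimited catalog (``dialect`` "csv" or "tsv") into records.

    Raises :class:`CatalogSchemaError` naming any missing required column;
    malformed values raise with the offending row number.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogSchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                VariantRecord(
                    gene=row["gene"],
                    variant_id=row["variant_id"],
                    location=row["location"],
                    allele_minor=row["allele_minor"],
                    allele_major=row["allele_major"],
                    risk_allele=row["risk_allele"],
                    freq_cases=float(row["freq_cases"]),
                    freq_controls=float(row["freq_controls"]),
                    n_cases=_opt_int(row.get("n_cases")),
                    n_controls=_opt_int(row.get("n_controls")),
                    reported_or=_opt_float(row.get("reported_or")),
                    printed_d=_opt_float(row.get("printed_d")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def write_catalog(records: Iterable[VariantRecord], path: str | Path, dialect: str = "csv") -> None:
    """Write records as delimited text; round-trips losslessly with read."""
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    df = pd.DataFrame([vars(r) for r in records], columns=_ALL_COLUMNS)
    df["n_cases"] = df["n_cases"].astype("Int64")
    df["n_controls"] = df["n_controls"].astype("Int64")
    df.to_csv(path, sep=sep, index=False)


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or pd.isna(value):
        return None
    return int(float(value))


def _opt_float(value) -> Optional[float]:
    if value is None or pd.isna(value):
        return None
    return float(value)


def load_reference_catalog() -> list[VariantRecord]:
    """The packaged 64-row catalog of top-ranked schizophrenia candidate-gene
    meta-analysis variants (SZGene top-45 genes, December 2011 snapshot),
    transcribed with the risk allele and its case/control frequencies."""
    path = Path(__file__).parent / "data" / "top45_szgene.csv"
    return read_catalog(path)
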