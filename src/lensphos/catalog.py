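"""Phosphosite catalog model, validation and summary statistics.

A catalog is a table of phosphosite observations: protein accession, tryptic
fragment coordinates, peptide sequence, site designation (``Ser-19``) and,
for differential catalogs, observed m/z, charge, identification score and the
cataract/normal abundance ratio. This module loads such tables, validates
their internal consistency, and derives the summary statistics a comparative
phosphoproteomics study reports: unique-site and protein counts,
serine/threonine/tyrosine distributions, two-fold differential classes, and
novelty against a known-site list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import masscalc

MANDATORY_COLUMNS = [
    "accession", "protein_name", "is_crystallin",
    "frag_start", "frag_end", "peptide", "designation",
]

_RANGE_RE = re.compile(r"^\s*(\d+)\s*[–\-]\s*(\d+)\s*$")


@dataclass
class PhosphositeRecord:
    """One catalog row: a phosphosite observation on a tryptic peptide."""

    accession: str
    protein_name: str
    is_crystallin: bool
    frag_start: int
    frag_end: int
    peptide: str
    designation: str
    mz: Optional[float] = None
    charge: Optional[int] = None
    score: Optional[float] = None
    pn_ratio: Optional[float] = None
    novel: Optional[bool] = None
    row: Optional[int] = None  # source row, for diagnostics

    def __post_init__(self) -> None:
        if self.frag_start > self.frag_end:
            raise ValueError(
                f"row {self.row}: inverted fragment range {self.frag_start}-{self.frag_end}"
            )
        if self.frag_end - self.frag_start + 1 != len(self.peptide):
            raise ValueError(
                f"row {self.row}: fragment range {self.frag_start}-{self.frag_end} "
                f"inconsistent with peptide length {len(self.peptide)}"
            )
        if self.pn_ratio is not None and not self.pn_ratio > 0:
            raise ValueError(f"row {self.row}: ratio must be > 0, got {self.pn_ratio}")

    @property
    def site(self) -> tuple[str, str]:
        """Unique site key (accession, designation)."""
        return (self.accession, self.designation)

    @property
    def residue_type(self) -> str:
        """One-letter code of the phosphorylated residue (from the designation)."""
        return masscalc.parse_designation(self.designation)[0]


def parse_fragment_range(text: str, row: Optional[int] = None) -> tuple[int, int]:
    """Parse ``12-22`` / ``12–22`` into (start, end); en-dash and hyphen accepted."""
    m = _RANGE_RE.match(str(text))
    if not m:
        raise ValueError(f"row {row}: unparseable fragment range {text!r}")
    return int(m.group(1)), int(m.group(2))


def _to_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"1", "yes", "true", "y"}:
        return True
    if text in {"0", "no", "false", "n", ""}:
        return False
    raise ValueError(f"cannot interpret {value!r} as a flag")


def load_catalog(source) -> list[PhosphositeRecord]:
    """Read a phosphosite catalog from a TSV path or file-like stream.

    The table may carry either separate ``frag_start``/``frag_end`` columns or
    a single ``fragment`` column with a ``12-22`` style range. Optional
    columns (mz, charge, score, pn_ratio, novel) may be absent entirely.
    """
    df = pd.read_csv(source, sep="\t", comment="#", dtype={"accession": str})
    if "fragment" in df.columns and "frag_start" not in df.columns:
        ranges = [parse_fragment_range(v, row=i + 1) for i, v in enumerate(df["fragment"])]
        df["frag_start"] = [r[0] for r in ranges]
        df["frag_end"] = [r[1] for r in ranges]
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    records = []
    for i, r in enumerate(df.itertuples(index=False), start=1):
        def opt(name, cast=float):
            v = getattr(r, name, None)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return cast(v)

        records.append(PhosphositeRecord(
            accession=str(r.accession),
            protein_name=str(r.protein_name),
            is_crystallin=bool(_to_bool(r.is_crystallin)),
            frag_start=int(r.frag_start),
            frag_end=int(r.frag_end),
            peptide=str(r.peptide),
            designation=str(r.designation),
            mz=opt("mz"),
            charge=opt("charge", int),
            score=opt("score"),
            pn_ratio=opt("pn_ratio"),
            novel=_to_bool(getattr(r, "novel", None)),
            row=i,
        ))
    return records


def load_packaged_catalog(name: str) -> list[PhosphositeRecord]:
    """Load one of the catalogs shipped with the package.

    ``name`` is ``"sites"`` for the full normal-lens phosphosite catalog or
    ``"differential"`` for the normal-vs-cataract comparison catalog.
    """
    fname = {"sites": "lens_sites.tsv", "differential": "lens_differential.tsv"}[name]
    with resources.files("lensphos.data").joinpath(fname).open("r") as fh:
        return load_catalog(fh)


def load_known_sites(source=None) -> list[tuple[str, str]]:
    """Known (accession, designation) pairs; defaults to the packaged list."""
    if source is None:
        with resources.files("lensphos.data").joinpath("known_sites.tsv").open("r") as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
    else:
        df = pd.read_csv(source, sep="\t", comment="#")
    return list(zip(df["accession"].astype(str), df["designation"].astype(str)))


# ---------------------------------------------------------------------------
# validation

@dataclass
class ValidationFinding:
    row: Optional[int]
    site: tuple[str, str]
    check: str
    message: str


@dataclass
class ValidationReport:
    passed: list[tuple[Optional[int], tuple[str, str]]] = field(default_factory=list)
    warnings: list[ValidationFinding] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"row": f.row, "accession": f.site[0], "designation": f.site[1],
             "check": f.check, "message": f.message}
            for f in self.warnings
        ]
        return pd.DataFrame(rows, columns=["row", "accession", "designation", "check", "message"])


def validate_catalog(records: Sequence[PhosphositeRecord],
                     proteins: Optional[dict[str, str]] = None) -> ValidationReport:
    """Check each record's internal consistency; warn, never drop.

    Checks: the designation position lies within the fragment range; the
    residue named by the designation matches the peptide at that offset; and,
    when protein sequences are supplied, the peptide equals the protein
    subsequence at its stated coordinates. Published catalogs can contain
    inconsistent rows, so findings are reported rather than raised.
    """
    report = ValidationReport()
    for rec in records:
        findings: list[ValidationFinding] = []
        residue, pos = masscalc.parse_designation(rec.designation)
        if not rec.frag_start <= pos <= rec.frag_end:
            findings.append(ValidationFinding(
                rec.row, rec.site, "designation_in_fragment",
                f"position {pos} outside fragment {rec.frag_start}-{rec.frag_end}"))
        else:
            actual = rec.peptide[pos - rec.frag_start]
            if actual != residue:
                findings.append(ValidationFinding(
                    rec.row, rec.site, "designation_residue",
                    f"designation names {residue} but peptide has {actual} at position {pos}"))
        if proteins is not None and rec.accession in proteins:
            seq = proteins[rec.accession]
            sub = seq[rec.frag_start - 1: rec.frag_end]
            if sub != rec.peptide:
                findings.append(ValidationFinding(
                    rec.row, rec.site, "peptide_in_protein",
                    f"protein subsequence {sub!r} != peptide {rec.peptide!r}"))
        if findings:
            report.warnings.extend(findings)
        else:
            report.passed.append((rec.row, rec.site))
    return report


# ---------------------------------------------------------------------------
# summaries

@dataclass
class CatalogSummary:
    n_sites: int
    n_proteins: int
    n_crystallin_proteins: int
    n_other_proteins: int
    residue_counts: dict[str, int]
    residue_percent: dict[str, float]          # 0.1% precision
    residue_percent_int: dict[str, int]        # nearest integer
    sites_per_protein: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "n_proteins": self.n_proteins,
            "n_crystallin_proteins": self.n_crystallin_proteins,
            "n_other_proteins": self.n_other_proteins,
            "residue_counts": self.residue_counts,
            "residue_percent": self.residue_percent,
            "residue_percent_int": self.residue_percent_int,
        }


def summarize(records: Sequence[PhosphositeRecord]) -> CatalogSummary:
    """Unique-site, protein and S/T/Y-distribution summary of a catalog.

    Sites are keyed by (accession, designation): a site covered by several
    peptide observations or charge states counts once.
    """
    if not records:
        raise ValueError("empty catalog")
    sites: dict[tuple[str, str], PhosphositeRecord] = {}
    for rec in records:
        sites.setdefault(rec.site, rec)
    crystallin = {r.accession for r in records if r.is_crystallin}
    other = {r.accession for r in records if not r.is_crystallin}
    counts = {"S": 0, "T": 0, "Y": 0}
    per_protein: dict[str, list[str]] = {}
    for (acc, desig), rec in sites.items():
        counts[rec.residue_type] += 1
        per_protein.setdefault(acc, []).append(desig)
    n = len(sites)
    percent = {k: round(100.0 * v / n, 1) for k, v in counts.items()}
    percent_int = {k: int(round(100.0 * v / n)) for k, v in counts.items()}
    return CatalogSummary(
        n_sites=n,
        n_proteins=len(crystallin | other),
        n_crystallin_proteins=len(crystallin),
        n_other_proteins=len(other),
        residue_counts=counts,
        residue_percent=percent,
        residue_percent_int=percent_int,
        sites_per_protein=per_protein,
    )


@dataclass
class DifferentialSummary:
    site_ratios: dict[tuple[str, str], float]
    classes: dict[tuple[str, str], str]
    n_increased: int
    n_decreased: int
    n_unchanged: int
    fold_threshold: float

    def to_dict(self) -> dict:
        return {
            "fold_threshold": self.fold_threshold,
            "n_sites": len(self.site_ratios),
            "n_increased": self.n_increased,
            "n_decreased": self.n_decreased,
            "n_unchanged": self.n_unchanged,
        }


def classify_differential(records: Sequence[PhosphositeRecord],
                          fold_threshold: float = 2.0) -> DifferentialSummary:
    """Classify each unique site as increased / decreased / unchanged.

    A site observed more than once (e.g. two charge states of the same
    phosphopeptide) gets the median of its ratios. Increased means
    ratio >= fold_threshold, decreased means ratio <= 1/fold_threshold,
    both inclusive.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    by_site: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        if rec.pn_ratio is None:
            raise ValueError(f"row {rec.row}: missing ratio")
        by_site.setdefault(rec.site, []).append(rec.pn_ratio)
    ratios = {site: float(np.median(vals)) for site, vals in by_site.items()}
    classes = {}
    for site, ratio in ratios.items():
        if ratio >= fold_threshold:
            classes[site] = "increased"
        elif ratio <= 1.0 / fold_threshold:
            classes[site] = "decreased"
        else:
            classes[site] = "unchanged"
    tally = {"increased": 0, "decreased": 0, "unchanged": 0}
    for c in classes.values():
        tally[c] += 1
    return DifferentialSummary(
        site_ratios=ratios,
        classes=classes,
        n_increased=tally["increased"],
        n_decreased=tally["decreased"],
        n_unchanged=tally["unchanged"],
        fold_threshold=fold_threshold,
    )


@dataclass
class NoveltySummary:
    novel_sites: list[tuple[str, str]]
    known_sites: list[tuple[str, str]]
    n_novel: int
    n_novel_crystallin: int
    n_novel_other: int
    n_crystallin_proteins_with_novel: int

    def to_dict(self) -> dict:
        return {
            "n_novel": self.n_novel,
            "n_novel_crystallin": self.n_novel_crystallin,
            "n_novel_other": self.n_novel_other,
            "n_crystallin_proteins_with_novel": self.n_crystallin_proteins_with_novel,
        }


def compare_novelty(records: Sequence[PhosphositeRecord],
                    known_sites: Iterable[tuple[str, str]]) -> NoveltySummary:
    """Mark each unique site novel iff absent from the known-site list."""
    known = set(known_sites)
    sites: dict[tuple[str, str], PhosphositeRecord] = {}
    for rec in records:
        sites.setdefault(rec.site, rec)
    novel = [s for s in sites if s not in known]
    novel_cryst = [s for s in novel if sites[s].is_crystallin]
    return NoveltySummary(
        novel_sites=sorted(novel),
        known_sites=sorted(s for s in sites if s in known),
        n_novel=len(novel),
        n_novel_crystallin=len(novel_cryst),
        n_novel_other=len(novel) - len(novel_cryst),
        n_crystallin_proteins_with_novel=len({acc for acc, _ in novel_cryst}),
    )


def mz_concordance(records: Sequence[PhosphositeRecord],
                   n_phospho: int = 1,
                   infer_oxidation: bool = True) -> pd.DataFrame:
    """Theoretical vs catalog m/z for every record carrying m/z and charge.

    Each peptide is assumed to carry ``n_phospho`` phosphate groups. When
    ``infer_oxidation`` is set, methionine-containing peptides are also tried
    with 0..#Met oxidations and the count minimising |deviation| is reported
    (variable Met oxidation is part of the identification search, and some
    catalog m/z values include it). Deviations are in Th and ppm; records
    without a charge are skipped with a note.
    """
    rows = []
    for rec in records:
        if rec.mz is None:
            continue
        if rec.charge is None:
            rows.append({"row": rec.row, "accession": rec.accession,
                         "designation": rec.designation, "peptide": rec.peptide,
                         "skipped": "no charge"})
            continue
        max_ox = rec.peptide.count("M") if infer_oxidation else 0
        best = None
        for n_ox in range(max_ox + 1):
            mass = (masscalc.peptide_monoisotopic_mass(rec.peptide)
                    + n_phospho * masscalc.PHOSPHO.delta
                    + n_ox * masscalc.OXIDATION.delta)
            theo = masscalc.compute_mz(mass, rec.charge)
            dev = theo - rec.mz
            if best is None or abs(dev) < abs(best[1]):
                best = (theo, dev, n_ox)
        theo, dev, n_ox = best
        rows.append({
            "row": rec.row, "accession": rec.accession, "designation": rec.designation,
            "peptide": rec.peptide, "charge": rec.charge, "mz_catalog": rec.mz,
            "mz_theoretical": round(theo, 4), "n_oxidation": n_ox,
            "deviation_th": dev, "deviation_ppm": 1e6 * dev / rec.mz,
            "skipped": "",
        })
    df = pd.DataFrame(rows)
    if "deviation_th" in df.columns:
        dev = df["deviation_th"].abs()
        df.attrs["median_abs_dev_th"] = float(dev.median())
        df.attrs["max_abs_dev_th"] = float(dev.max())
    return df
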