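"""Peptidoform-level aggregation and description.

A peptidoform is a peptide sequence paired with an open-search delta mass
rounded to one decimal (ties away from zero). This module turns PSM
records into peptidoform-by-sample count matrices and computes protein
coverage, peptide positions, modification-state classes, bait-vs-prey
enrichment summaries, and delta-mass annotations.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .io_formats import ExperimentDesign, PSMRecord, ProteinDB

logger = logging.getLogger(__name__)

#: Mass spacing of an isotopic precursor mis-selection error (Da).
ISOTOPE_SPACING = 1.00335
#: Default half-width tolerance for delta-mass matching (Da).
DEFAULT_TOLERANCE = 0.05
#: Default integer isotope-shift range checked by :func:`is_isotopic_error`.
DEFAULT_K_RANGE = range(-1, 4)

#: Monoisotopic residue masses of the 20 standard amino acids (Da).
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}


def round_delta(delta_mass: float, decimals: int = 1) -> float:
    """Round a delta mass with ties away from zero; -0.0 becomes +0.0."""
    q = Decimal(1).scaleb(-decimals)
    rounded = float(Decimal(repr(delta_mass)).quantize(q, rounding=ROUND_HALF_UP))
    return rounded + 0.0  # normalizes -0.0


@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence with its rounded delta-mass key."""

    peptide: str
    delta_key: float
    localization: str = ""

    @property
    def key(self) -> str:
        return f"{self.peptide}@{self.delta_key:+.1f}"

    def __str__(self) -> str:
        return self.key


def make_peptidoform_key(
    peptide: str, delta_mass: float, localization: str = "", decimals: int = 1
) -> Peptidoform:
    """Build a peptidoform from a peptide and raw delta mass.

    The delta is rounded to ``decimals`` places (default one, i.e. 0.1 Da
    bins) with ties away from zero; a rounded -0.0 is normalized to +0.0
    so the unmodified key always renders as ``PEPTIDE@+0.0``.
    """
    if not math.isfinite(delta_mass):
        raise ValueError("delta mass must be finite")
    return Peptidoform(
        peptide=peptide,
        delta_key=round_delta(delta_mass, decimals),
        localization=localization,
    )


def is_isotopic_error(
    delta_mass: float,
    tolerance: float = DEFAULT_TOLERANCE,
    k_range: Iterable[int] = DEFAULT_K_RANGE,
) -> bool:
    """True if ``delta_mass`` matches an integer isotope shift (incl. zero)."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    ks = set(k_range) | {0}
    return any(abs(delta_mass - k * ISOTOPE_SPACING) <= tolerance for k in ks)


ModificationState = Literal["unmodified", "modified", "multiple"]


def classify_modification_state(
    peptidoforms: Iterable[Peptidoform],
    tolerance: float = DEFAULT_TOLERANCE,
    k_range: Iterable[int] = DEFAULT_K_RANGE,
) -> ModificationState:
    """Classify the detection states of one peptide across its peptidoforms.

    Isotopic-error delta keys collapse into the unmodified state first.
    """
    forms = list(peptidoforms)
    if not forms:
        raise ValueError("empty peptidoform set")
    peptides = {p.peptide for p in forms}
    if len(peptides) > 1:
        raise ValueError(f"peptidoforms span multiple peptides: {sorted(peptides)}")
    states: set[object] = set()
    for p in forms:
        if is_isotopic_error(p.delta_key, tolerance, k_range):
            states.add("unmodified")
        else:
            states.add(p.delta_key)
    modified = [s for s in states if s != "unmodified"]
    if not modified:
        return "unmodified"
    if len(modified) == 1 and "unmodified" not in states:
        return "modified"
    return "multiple"


def matches_bait(record: PSMRecord, design: ExperimentDesign) -> bool:
    """Bait test: gene symbol match OR accession match incl. isoform suffix."""
    if record.gene and record.gene == design.bait_gene:
        return True
    acc = record.assigned_protein
    if not acc:
        return False
    base = acc.split("-")[0]
    for bait_acc in design.bait_accessions:
        if acc == bait_acc or base == bait_acc.split("-")[0]:
            return True
    return False


@dataclass
class CountMatrix:
    """Peptidoform-by-sample PSM counts backed by a pandas DataFrame.

    ``df`` is indexed by peptidoform key string; ``peptidoforms`` maps each
    key back to its :class:`Peptidoform`. Values are raw integers after
    aggregation and may become fractional after normalization.
    """

    df: pd.DataFrame
    peptidoforms: dict[str, Peptidoform]
    scope: str = "bait"
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.df.values < 0).any():
            raise ValueError("count matrix contains negative values")
        if self.df.index.has_duplicates:
            raise ValueError("duplicate peptidoform keys")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def keys(self) -> list[str]:
        return list(self.df.index)

    def total(self, sample_id: str) -> float:
        return float(self.df[sample_id].sum())

    def row_totals(self) -> pd.Series:
        return self.df.sum(axis=1)

    def subset_rows(self, keys: Sequence[str], **overrides) -> "CountMatrix":
        keys = [k for k in self.keys if k in set(keys)]
        kwargs = dict(scope=self.scope, normalized=self.normalized)
        kwargs.update(overrides)
        return CountMatrix(
            df=self.df.loc[keys].copy(),
            peptidoforms={k: self.peptidoforms[k] for k in keys},
            **kwargs,
        )


def aggregate_counts(
    records: Iterable[PSMRecord],
    design: ExperimentDesign,
    scope: Literal["bait", "all"] = "bait",
    decimals: int = 1,
) -> CountMatrix:
    """Count PSMs per peptidoform key per sample.

    With ``scope="bait"`` only records matching the bait (gene symbol or
    accession, isoforms included) are counted; the matrix total then
    equals the number of bait-matching PSMs (count conservation).
    """
    sample_ids = design.sample_ids
    known = set(sample_ids)
    counts: dict[str, dict[str, int]] = {}
    forms: dict[str, Peptidoform] = {}
    n_in_scope = 0
    for rec in records:
        if rec.sample_id not in known:
            raise ValueError(f"record sample {rec.sample_id!r} not in design")
        if scope == "bait" and not matches_bait(rec, design):
            continue
        n_in_scope += 1
        pf = make_peptidoform_key(rec.peptide, rec.delta_mass, rec.localization, decimals)
        key = pf.key
        if key not in forms:
            forms[key] = pf
            counts[key] = dict.fromkeys(sample_ids, 0)
        elif not forms[key].localization and pf.localization:
            forms[key] = pf  # prefer a localized representative
        counts[key][rec.sample_id] += 1
    if n_in_scope == 0:
        logger.warning("no PSMs in scope %r; empty count matrix", scope)
    df = pd.DataFrame.from_dict(counts, orient="index", columns=sample_ids, dtype=float)
    if df.empty:
        df = pd.DataFrame(index=pd.Index([], dtype=object), columns=sample_ids, dtype=float)
    return CountMatrix(df=df, peptidoforms=forms, scope=scope)


def write_count_matrix(counts: CountMatrix, path) -> None:
    """Persist a count matrix as TSV (metadata columns + one per sample)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "\t".join(
                ["peptidoform", "peptide", "delta_mass", "localization",
                 "scope", "normalized"] + counts.sample_ids
            ) + "\n"
        )
        for key in counts.keys:
            pf = counts.peptidoforms[key]
            row = [key, pf.peptide, f"{pf.delta_key:+.1f}", pf.localization,
                   counts.scope, str(counts.normalized)]
            row += [repr(float(counts.df.at[key, s])) for s in counts.sample_ids]
            fh.write("\t".join(row) + "\n")


def read_count_matrix(path) -> CountMatrix:
    """Read a TSV produced by :func:`write_count_matrix`."""
    meta_cols = ["peptidoform", "peptide", "delta_mass", "localization",
                 "scope", "normalized"]
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in meta_cols},
                     keep_default_na=False)
    sample_ids = [c for c in df.columns if c not in meta_cols]
    forms = {
        row["peptidoform"]: Peptidoform(
            peptide=row["peptide"],
            delta_key=float(row["delta_mass"]),
            localization=row["localization"],
        )
        for _, row in df.iterrows()
    }
    values = df[sample_ids].astype(float)
    values.index = df["peptidoform"]
    values.index.name = None
    scope = df["scope"].iloc[0] if len(df) else "bait"
    normalized = (df["normalized"].iloc[0] == "True") if len(df) else False
    return CountMatrix(df=values, peptidoforms=forms, scope=scope,
                       normalized=normalized)


@dataclass(frozen=True)
class CoverageResult:
    gene: str
    percent_coverage: float
    covered_positions: frozenset[int]
    isoform_length: int


def _all_occurrences(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) 0-based match positions."""
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def compute_coverage(
    peptides: Iterable[str] | Iterable[PSMRecord],
    proteindb: ProteinDB,
    gene: str,
) -> CoverageResult:
    """Fraction of the gene's longest isoform covered by detected peptides.

    Every exact substring occurrence of every distinct peptide contributes
    its residue indices (1-based); unmatched peptides are logged and
    ignored.
    """
    if gene not in proteindb:
        raise KeyError(f"gene {gene!r} not in protein database")
    isoform = proteindb.longest_isoform(gene)
    covered: set[int] = set()
    for item in peptides:
        pep = item.peptide if isinstance(item, PSMRecord) else item
        hits = _all_occurrences(isoform, pep)
        if not hits:
            logger.warning("peptide %s not found in longest %s isoform", pep, gene)
            continue
        for start in hits:
            covered.update(range(start + 1, start + len(pep) + 1))
    return CoverageResult(
        gene=gene,
        percent_coverage=100.0 * len(covered) / len(isoform),
        covered_positions=frozenset(covered),
        isoform_length=len(isoform),
    )


@dataclass(frozen=True)
class PeptidePosition:
    peptide: str
    start: int  # 1-based, first occurrence
    end: int  # 1-based inclusive
    relative_midpoint: float


def peptide_relative_positions(
    peptides: Iterable[str],
    proteindb: ProteinDB,
    gene: str,
) -> list[PeptidePosition]:
    """Map distinct peptides to their first-match position on the longest isoform."""
    if gene not in proteindb:
        raise KeyError(f"gene {gene!r} not in protein database")
    isoform = proteindb.longest_isoform(gene)
    out: list[PeptidePosition] = []
    seen: set[str] = set()
    for pep in peptides:
        if pep in seen:
            continue
        seen.add(pep)
        i = isoform.find(pep)
        if i < 0:
            logger.warning("peptide %s not found in longest %s isoform", pep, gene)
            continue
        start, end = i + 1, i + len(pep)
        out.append(
            PeptidePosition(
                peptide=pep,
                start=start,
                end=end,
                relative_midpoint=((start + end) / 2) / len(isoform),
            )
        )
    return out


@dataclass(frozen=True)
class KnownMod:
    """A named modification with mass and residue specificity."""

    name: str
    mono_mass: float
    residues: frozenset[str]  # single letters and/or "N-term"
    provenance: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.mono_mass):
            raise ValueError("mono_mass must be finite")
        if not self.residues:
            raise ValueError("residues must be non-empty")


def load_known_mods(path: Optional[str] = None) -> list[KnownMod]:
    """Load the known-modification table (bundled TSV resource by default)."""
    if path is None:
        source = resources.files("baitform.data").joinpath("known_mods.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    mods: list[KnownMod] = []
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        mods.append(
            KnownMod(
                name=row["name"],
                mono_mass=float(row["mono_mass"]),
                residues=frozenset(r.strip() for r in row["residues"].split(",") if r.strip()),
                provenance=row.get("provenance", ""),
            )
        )
    return mods


def substitution_mods() -> list[KnownMod]:
    """Single amino-acid substitutions as delta-mass candidates.

    Generated from the 20 standard monoisotopic residue masses: for every
    ordered pair (X, Y) with distinct mass, mass(Y) - mass(X) localized
    on X.
    """
    subs: list[KnownMod] = []
    for x, mx in RESIDUE_MASSES.items():
        for y, my in RESIDUE_MASSES.items():
            if x == y or abs(my - mx) < 1e-9:
                continue
            subs.append(
                KnownMod(
                    name=f"substitution {x}->{y}",
                    mono_mass=my - mx,
                    residues=frozenset({x}),
                    provenance="computed from residue masses",
                )
            )
    return subs


DEFAULT_FIXED_MODS = (
    KnownMod("carbamidomethyl", 57.02146, frozenset({"C"}), "fixed alkylation"),
)


@dataclass(frozen=True)
class Annotation:
    """One candidate explanation of an observed delta mass."""

    name: str
    kind: Literal["unmodified", "isotopic_error", "modification", "substitution"]
    candidate_mass: float
    mass_error: float
    displaces_fixed: Optional[str] = None  # name of the displaced fixed mod


def _residue_compatible(mod: KnownMod, residue: Optional[str]) -> bool:
    if residue is None or residue == "unknown":
        return True
    return residue in mod.residues


def annotate_delta_mass(
    delta_key: float,
    localized_residue: Optional[str] = None,
    fixed_mods: Sequence[KnownMod] = DEFAULT_FIXED_MODS,
    known_mods: Optional[Sequence[KnownMod]] = None,
    tolerance: float = DEFAULT_TOLERANCE,
    include_substitutions: bool = True,
) -> list[Annotation]:
    """Candidate explanations for an observed (rounded) delta mass.

    Candidates are known modifications and single amino-acid substitutions
    within ``tolerance`` of the delta, evaluated both directly and after
    adding back any fixed modification whose residue matches the localized
    residue (the fixed-mod displacement case, e.g. cysteic acid under
    fixed carbamidomethyl reporting about -9 Da). Isotopic errors and the
    zero shift are annotated as such. The result is sorted by absolute
    mass error then name, so it is invariant to candidate table order.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if known_mods is None:
        known_mods = load_known_mods()
    candidates = list(known_mods)
    if include_substitutions:
        candidates += substitution_mods()

    out: list[Annotation] = []
    if abs(delta_key) <= tolerance:
        out.append(Annotation("unmodified", "unmodified", 0.0, abs(delta_key)))
    elif is_isotopic_error(delta_key, tolerance):
        k = round(delta_key / ISOTOPE_SPACING)
        out.append(
            Annotation(
                f"isotopic error ({k:+d})",
                "isotopic_error",
                k * ISOTOPE_SPACING,
                abs(delta_key - k * ISOTOPE_SPACING),
            )
        )

    applicable_fixed = [
        fm for fm in fixed_mods
        if localized_residue is not None and localized_residue in fm.residues
    ]
    for cand in candidates:
        kind = "substitution" if cand.name.startswith("substitution") else "modification"
        err = abs(delta_key - cand.mono_mass)
        if err <= tolerance and _residue_compatible(cand, localized_residue):
            out.append(Annotation(cand.name, kind, cand.mono_mass, err))
        for fm in applicable_fixed:
            if cand.name == fm.name:
                continue
            err2 = abs(delta_key + fm.mono_mass - cand.mono_mass)
            if err2 <= tolerance and _residue_compatible(cand, localized_residue):
                out.append(
                    Annotation(cand.name, kind, cand.mono_mass, err2, displaces_fixed=fm.name)
                )
    out.sort(key=lambda a: (a.mass_error, a.name, a.displaces_fixed or ""))
    return out


@dataclass(frozen=True)
class EnrichmentSummary:
    sample_id: str
    bait_psm_count: int
    prey_psm_counts: tuple[int, ...]  # per non-bait protein, descending


def summarize_enrichment(
    records: Iterable[PSMRecord],
    design: ExperimentDesign,
) -> list[EnrichmentSummary]:
    """Per-sample bait PSM total vs per-prey-protein PSM distribution."""
    bait: dict[str, int] = dict.fromkeys(design.sample_ids, 0)
    prey: dict[str, dict[str, int]] = {s: {} for s in design.sample_ids}
    for rec in records:
        if rec.sample_id not in bait:
            raise ValueError(f"record sample {rec.sample_id!r} not in design")
        if matches_bait(rec, design):
            bait[rec.sample_id] += 1
        else:
            protein = rec.assigned_protein or rec.gene or "?"
            prey[rec.sample_id][protein] = prey[rec.sample_id].get(protein, 0) + 1
    return [
        EnrichmentSummary(
            sample_id=s,
            bait_psm_count=bait[s],
            prey_psm_counts=tuple(sorted(prey[s].values(), reverse=True)),
        )
        for s in design.sample_ids
    ]
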