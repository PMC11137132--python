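"""Readers and writers for the external formats the workflow touches.

Covers FragPipe-style ``psm.tsv`` tables, protein FASTA databases with
UniProt-style headers, experiment-design manifests (TSV or YAML), the
SAINTexpress spectral-count input triple, SAINTexpress ``list`` output,
and the results TSV.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

logger = logging.getLogger(__name__)

_PEPTIDE_RE = re.compile(r"^[A-Z]+$")

#: Default column-name mapping for the FragPipe psm.tsv dialect.
FRAGPIPE_COLUMNS: Mapping[str, str] = {
    "spectrum_id": "Spectrum",
    "peptide": "Peptide",
    "modified_peptide": "Modified Peptide",
    "delta_mass": "Delta Mass",
    "assigned_protein": "Protein",
    "gene": "Gene",
    "mapped_proteins": "Mapped Proteins",
    "localization": "MSFragger Localization",
    "observed_modifications": "Observed Modifications",
    "intensity": "Intensity",
}

#: Columns that must be present in every PSM table.
MANDATORY_FIELDS = ("peptide", "delta_mass", "assigned_protein", "gene")


class FormatError(ValueError):
    """Raised when an input file does not conform to its expected dialect."""


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match row from an open- or closed-search table."""

    peptide: str
    delta_mass: float
    sample_id: str = ""
    spectrum_id: str = ""
    modified_peptide: str = ""
    assigned_protein: str = ""
    gene: str = ""
    mapped_proteins: tuple[str, ...] = ()
    localization: str = ""
    observed_modifications: str = ""
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if not _PEPTIDE_RE.match(self.peptide):
            raise ValueError(f"invalid peptide sequence: {self.peptide!r}")
        if not math.isfinite(self.delta_mass):
            raise ValueError(f"delta mass not finite for peptide {self.peptide}")


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    condition: str
    replicate: int = 1
    psm_path: str = ""


@dataclass
class ExperimentDesign:
    """Sample-to-condition assignment plus bait identity and comparisons."""

    samples: list[SampleInfo]
    bait_gene: str
    bait_accessions: frozenset[str]
    comparisons: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bait_accessions = frozenset(self.bait_accessions)
        if not self.bait_accessions:
            raise ValueError("bait_accessions must be non-empty")
        conditions = {s.condition for s in self.samples}
        for test, control in self.comparisons:
            for cond in (test, control):
                if cond not in conditions:
                    raise ValueError(
                        f"comparison references unknown condition {cond!r}"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.condition, None)
        return list(seen)

    def condition_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.condition
        raise KeyError(sample_id)

    def samples_in(self, condition: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.condition == condition]


_UNIPROT_HEADER_RE = re.compile(r"^(?:sp|tr)\|(?P<acc>[^|]+)\|\S*")
_GENE_RE = re.compile(r"\bGN=(\S+)")


class ProteinDB:
    """Protein sequences grouped per gene with longest-isoform lookup.

    Longest-isoform ties are broken lexicographically by accession so the
    result is deterministic and independent of FASTA record order.
    """

    def __init__(self) -> None:
        self._by_gene: dict[str, list[tuple[str, str]]] = {}
        self._by_accession: dict[str, str] = {}

    def add(self, accession: str, gene: str, sequence: str) -> None:
        if accession in self._by_accession:
            raise FormatError(f"duplicate accession {accession!r}")
        if not _PEPTIDE_RE.match(sequence):
            raise FormatError(
                f"sequence for {accession!r} contains non-alphabetic characters"
            )
        self._by_accession[accession] = sequence
        self._by_gene.setdefault(gene, []).append((accession, sequence))

    @property
    def genes(self) -> list[str]:
        return list(self._by_gene)

    def isoforms(self, gene: str) -> list[tuple[str, str]]:
        return list(self._by_gene[gene])

    def sequence(self, accession: str) -> str:
        return self._by_accession[accession]

    def longest_isoform(self, gene: str) -> str:
        if gene not in self._by_gene:
            raise KeyError(f"gene {gene!r} not in database")
        # max length; ties resolved toward the lexicographically smallest accession
        best = min(self._by_gene[gene], key=lambda it: (-len(it[1]), it[0]))
        return best[1]

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_gene

    def __len__(self) -> int:
        return len(self._by_accession)


def read_fasta(path: str | Path, gene_pattern: Optional[str] = None) -> ProteinDB:
    """Read a FASTA file into a :class:`ProteinDB`.

    UniProt-style headers (``>sp|ACC|NAME ... GN=GENE``) are parsed by
    default; ``gene_pattern`` may supply an alternative regex whose first
    group captures the gene symbol. Entries without a recognizable gene
    fall back to the accession itself as the gene key.
    """
    gene_re = re.compile(gene_pattern) if gene_pattern else _GENE_RE
    db = ProteinDB()
    accession = gene = None
    chunks: list[str] = []

    def flush() -> None:
        if accession is not None:
            db.add(accession, gene or accession, "".join(chunks).upper())

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                m = _UNIPROT_HEADER_RE.match(header)
                accession = m.group("acc") if m else header.split()[0]
                gm = gene_re.search(header)
                gene = gm.group(1) if gm else None
                chunks = []
            else:
                chunks.append(line.strip())
    flush()
    return db


def write_fasta(path: str | Path, entries: Iterable[tuple[str, str, str]]) -> None:
    """Write (accession, gene, sequence) triples with UniProt-style headers."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for accession, gene, sequence in entries:
            fh.write(f">sp|{accession}|{accession}_SYN synthetic GN={gene}\n")
            for i in range(0, len(sequence), 60):
                fh.write(sequence[i : i + 60] + "\n")


def read_psm_table(
    path: str | Path,
    sample_id: str,
    columns: Mapping[str, str] = FRAGPIPE_COLUMNS,
) -> list[PSMRecord]:
    """Read one FragPipe-dialect ``psm.tsv`` into PSM records.

    One record is produced per data row; missing optional columns yield
    empty fields. Mandatory columns are Peptide, Delta Mass, Protein and
    Gene (under the configured mapping).
    """
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise FormatError(f"{path}: empty file, expected a header row")
        header = header_line.split("\t")
        index = {name: i for i, name in enumerate(header)}

        for field_name in MANDATORY_FIELDS:
            col = columns[field_name]
            if col not in index:
                raise FormatError(f"{path}: missing mandatory column {col!r}")

        def cell(parts: Sequence[str], field_name: str) -> str:
            col = columns.get(field_name)
            if col is None or col not in index:
                return ""
            i = index[col]
            return parts[i] if i < len(parts) else ""

        records: list[PSMRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            raw_delta = cell(parts, "delta_mass")
            try:
                delta = float(raw_delta) if raw_delta else 0.0
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: unparsable delta mass {raw_delta!r}"
                ) from exc
            raw_intensity = cell(parts, "intensity")
            try:
                intensity = float(raw_intensity) if raw_intensity else None
            except ValueError:
                intensity = None
            mapped = cell(parts, "mapped_proteins")
            records.append(
                PSMRecord(
                    peptide=cell(parts, "peptide"),
                    delta_mass=delta,
                    sample_id=sample_id,
                    spectrum_id=cell(parts, "spectrum_id"),
                    modified_peptide=cell(parts, "modified_peptide"),
                    assigned_protein=cell(parts, "assigned_protein"),
                    gene=cell(parts, "gene"),
                    mapped_proteins=tuple(
                        p.strip() for p in mapped.split(",") if p.strip()
                    ),
                    localization=cell(parts, "localization"),
                    observed_modifications=cell(parts, "observed_modifications"),
                    intensity=intensity,
                )
            )
    return records


def write_psm_table(
    path: str | Path,
    records: Iterable[PSMRecord],
    columns: Mapping[str, str] = FRAGPIPE_COLUMNS,
) -> None:
    """Write PSM records back out in the FragPipe dialect."""
    field_order = list(columns)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns[f] for f in field_order) + "\n")
        for rec in records:
            cells = []
            for f in field_order:
                v = getattr(rec, f)
                if f == "mapped_proteins":
                    cells.append(", ".join(v))
                elif f == "delta_mass":
                    cells.append(repr(v))
                elif f == "intensity":
                    cells.append("" if v is None else repr(v))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_design(path: str | Path) -> tuple[ExperimentDesign, dict[str, str]]:
    """Read a design manifest (YAML or TSV).

    Returns the design plus a mapping sample_id -> psm table path (relative
    paths are resolved against the manifest's directory).

    YAML layout::

        bait_gene: HRAS
        bait_accessions: [P01112]
        comparisons: [[G12D, WT]]
        samples:
          - {sample_id: s1, psm_path: s1.psm.tsv, condition: WT, replicate: 1}

    The TSV layout has columns sample_id, psm_path, condition, replicate,
    bait_gene, bait_accessions (semicolon-separated), and optional
    comparison (``test~control``, repeated rows allowed).
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        samples = [
            SampleInfo(
                sample_id=str(s["sample_id"]),
                condition=str(s["condition"]),
                replicate=int(s.get("replicate", 1)),
                psm_path=str(s.get("psm_path", "")),
            )
            for s in doc.get("samples", [])
        ]
        comparisons = [tuple(c) for c in doc.get("comparisons", [])]
        design = ExperimentDesign(
            samples=samples,
            bait_gene=str(doc["bait_gene"]),
            bait_accessions=frozenset(str(a) for a in doc.get("bait_accessions", [])),
            comparisons=comparisons,
        )
    else:
        import csv

        samples = []
        bait_gene = ""
        bait_accessions: set[str] = set()
        comparisons = []
        with open(path, encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                samples.append(
                    SampleInfo(
                        sample_id=row["sample_id"],
                        condition=row["condition"],
                        replicate=int(row.get("replicate") or 1),
                        psm_path=row.get("psm_path") or "",
                    )
                )
                bait_gene = row.get("bait_gene") or bait_gene
                accs = row.get("bait_accessions") or ""
                bait_accessions.update(a for a in accs.split(";") if a)
                comp = row.get("comparison") or ""
                if comp and "~" in comp:
                    test, control = comp.split("~", 1)
                    if (test, control) not in comparisons:
                        comparisons.append((test, control))
        design = ExperimentDesign(
            samples=samples,
            bait_gene=bait_gene,
            bait_accessions=frozenset(bait_accessions),
            comparisons=comparisons,
        )
    paths = {
        s.sample_id: str((path.parent / s.psm_path) if s.psm_path else "")
        for s in design.samples
    }
    return design, paths


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def write_saint_inputs(
    counts,
    design: ExperimentDesign,
    comparison: tuple[str, str],
    out_dir: str | Path,
) -> tuple[Path, Path, Path]:
    """Write the SAINTexpress spectral-count input triple for one comparison.

    The peptidoform key plays the prey role: the interaction file rows are
    (IP_name, bait_name, prey_name, count), the prey file rows are
    (prey_name, peptide length, gene-like label), and the bait file marks
    test-condition samples ``T`` and control-condition samples ``C``.
    Counts are rounded half-away-from-zero to integers for the external
    tool; zero-count rows are omitted.
    """
    test, control = comparison
    if comparison not in design.comparisons:
        raise ValueError(f"comparison {comparison!r} not declared in design")
    if counts.df.shape[0] == 0:
        raise ValueError("empty bait peptidoform set: nothing to score")
    sample_ids = design.samples_in(test) + design.samples_in(control)
    missing = [s for s in sample_ids if s not in counts.df.columns]
    if missing:
        raise ValueError(f"samples absent from count matrix: {missing}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inter_path = out_dir / "interaction.txt"
    prey_path = out_dir / "prey.txt"
    bait_path = out_dir / "bait.txt"

    bait_name = design.bait_gene
    with open(inter_path, "w", encoding="utf-8", newline="\n") as fh:
        for key, pf in counts.peptidoforms.items():
            for s in sample_ids:
                n = round_half_away(float(counts.df.at[key, s]))
                if n > 0:
                    fh.write(f"{s}\t{bait_name}\t{key}\t{n}\n")
    with open(prey_path, "w", encoding="utf-8", newline="\n") as fh:
        for key, pf in counts.peptidoforms.items():
            fh.write(f"{key}\t{len(pf.peptide)}\t{key}\n")
    with open(bait_path, "w", encoding="utf-8", newline="\n") as fh:
        for s in design.samples_in(test):
            fh.write(f"{s}\t{bait_name}\tT\n")
        for s in design.samples_in(control):
            fh.write(f"{s}\t{bait_name}\tC\n")
    return inter_path, prey_path, bait_path


@dataclass(frozen=True)
class SaintRecord:
    peptidoform_key: str
    avgp: float
    bfdr: Optional[float]
    fold_change: Optional[float] = None


def read_saint_output(path: str | Path) -> list[SaintRecord]:
    """Parse a SAINTexpress ``list`` output file.

    A malformed BFDR cell (e.g. ``NA``) yields a record with BFDR missing
    and a logged warning rather than a hard failure.
    """
    records: list[SaintRecord] = []
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            return records
        header = header_line.split("\t")
        index = {name: i for i, name in enumerate(header)}
        if "BFDR" not in index:
            raise FormatError(f"{path}: missing BFDR column")
        if "Prey" not in index or "AvgP" not in index:
            raise FormatError(f"{path}: missing Prey/AvgP column")
        fc_idx = index.get("FoldChange")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                bfdr: Optional[float] = float(parts[index["BFDR"]])
            except ValueError:
                logger.warning(
                    "%s:%d: unparsable BFDR %r, marked missing",
                    path, lineno, parts[index["BFDR"]],
                )
                bfdr = None
            fc = None
            if fc_idx is not None and fc_idx < len(parts):
                try:
                    fc = float(parts[fc_idx])
                except ValueError:
                    fc = None
            records.append(
                SaintRecord(
                    peptidoform_key=parts[index["Prey"]],
                    avgp=float(parts[index["AvgP"]]),
                    bfdr=bfdr,
                    fold_change=fc,
                )
            )
    return records


RESULTS_COLUMNS = [
    "peptidoform",
    "peptide",
    "delta_mass",
    "localization",
    "test_condition",
    "control_condition",
    "avgp",
    "bfdr",
    "log2fc",
    "mean_test",
    "mean_control",
    "significant",
]


def write_results_tsv(path: str | Path, results, design: ExperimentDesign, counts=None) -> None:
    """Write differential results with optional per-sample raw counts."""
    sample_cols = design.sample_ids if counts is not None else []
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(RESULTS_COLUMNS + [f"count_{s}" for s in sample_cols]) + "\n")
        for r in results:
            row = [
                r.peptidoform.key,
                r.peptidoform.peptide,
                f"{r.peptidoform.delta_key:+.1f}",
                r.peptidoform.localization or "",
                r.test_condition,
                r.control_condition,
                f"{r.avgp:.6g}",
                "" if r.bfdr is None else f"{r.bfdr:.6g}",
                f"{r.log2fc:.6g}",
                f"{r.mean_test:.6g}",
                f"{r.mean_control:.6g}",
                str(bool(r.significant)),
            ]
            for s in sample_cols:
                key = r.peptidoform.key
                v = counts.df.at[key, s] if key in counts.df.index else 0.0
                row.append(f"{float(v):.6g}")
            fh.write("\t".join(row) + "\n")
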