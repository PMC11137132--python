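"""Synthetic open-search PSM datasets with controlled peptidoform structure.

Generates FragPipe-dialect PSM tables, a matching FASTA and a design
manifest in which every differential peptidoform is known, so the whole
pipeline can be exercised and power-tested without any external data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .io_formats import (
    ExperimentDesign,
    PSMRecord,
    ProteinDB,
    SampleInfo,
    write_fasta,
    write_psm_table,
)
from .peptidoform import make_peptidoform_key

# A 189-residue RAS-like GTPase sequence used as the default synthetic bait;
# tryptic digestion yields LVVVGAGGVGK as its second peptide.
DEFAULT_BAIT_SEQUENCE = (
    "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPTIEDSYRKQVVIDGETCLLDILDTAG"
    "QEEYSAMRDQYMRTGEGFLCVFAINNTKSFEDIHQYREQIKRVKDSDDVPMVLVGNKCDL"
    "AARTVESRQAQDLARSYGIPYIETSAKTRQGVEDAFYTLVREIRQHKLRKLNPPDESGPG"
    "CMSCKCVLS"
)

MUTATION_PEPTIDE = "LVVVGAGGVGK"
MUTATION_DELTA = 58.0055  # G->D substitution mass

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def tryptic_digest(
    sequence: str, min_length: int = 7, max_length: int = 30
) -> list[str]:
    """In-silico tryptic digestion: cleave after K/R except before P.

    Returns fully-cleaved peptides with lengths in [min_length, max_length],
    in N-to-C order.
    """
    peptides: list[str] = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 >= len(sequence) or sequence[i + 1] != "P"):
            peptides.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        peptides.append(sequence[start:])
    return [p for p in peptides if min_length <= len(p) <= max_length]


@dataclass
class DeltaSpec:
    """One modification population in the simulated delta-mass menu."""

    delta: float
    residue: Optional[str]  # apply to peptides containing this residue; None = all
    rate: float  # expected PSMs per sample at baseline


@dataclass
class DifferentialSpec:
    """Marks one peptidoform as condition-dependent."""

    index: int  # into the generated peptidoform list
    fold: float  # rate multiplier applied in `condition`
    condition: str


@dataclass
class SimConfig:
    seed: int = 0
    conditions: list[tuple[str, int]] = field(
        default_factory=lambda: [("ctrl", 3), ("test", 3)]
    )
    bait_gene: str = "BAIT1"
    bait_accession: str = "B00001"
    bait_sequence: str = DEFAULT_BAIT_SEQUENCE
    n_bait_peptides: Optional[int] = 8
    base_rate: float = 10.0
    delta_menu: list[DeltaSpec] = field(
        default_factory=lambda: [
            DeltaSpec(43.0058, None, 2.0),        # N-term carbamylation-like
            DeltaSpec(15.9949, "M", 3.0),         # oxidation
            DeltaSpec(1.00335, None, 1.5),        # isotopic error population
        ]
    )
    differential: list[DifferentialSpec] = field(default_factory=list)
    n_prey_proteins: int = 30
    prey_log_mean: float = 1.0   # lognormal parameters of per-protein PSM rate
    prey_log_sd: float = 0.8
    sample_depth_jitter: float = 0.05

    def __post_init__(self) -> None:
        if any(n < 1 for _, n in self.conditions):
            raise ValueError("replicate counts must be >= 1")
        if self.base_rate < 0 or any(d.rate < 0 for d in self.delta_menu):
            raise ValueError("rates must be non-negative")
        if any(d.fold <= 0 for d in self.differential):
            raise ValueError("fold changes must be positive")


@dataclass
class TruthEntry:
    peptidoform_key: str
    condition: str  # condition in which the rate is scaled
    fold: float


@dataclass
class SyntheticDataset:
    records: dict[str, list[PSMRecord]]  # sample_id -> PSMs
    proteindb: ProteinDB
    design: ExperimentDesign
    truth: list[TruthEntry]
    fasta_entries: list[tuple[str, str, str]]  # (accession, gene, sequence)

    def all_records(self) -> list[PSMRecord]:
        out: list[PSMRecord] = []
        for s in self.design.sample_ids:
            out.extend(self.records[s])
        return out


def _build_peptidoform_menu(config: SimConfig) -> list[tuple[str, float, str, float]]:
    """(peptide, delta, localization, baseline rate) for every simulated form."""
    peptides = tryptic_digest(config.bait_sequence)
    if not peptides:
        raise ValueError("bait sequence yields no valid tryptic peptides")
    if config.n_bait_peptides is not None:
        peptides = peptides[: config.n_bait_peptides]
    menu: list[tuple[str, float, str, float]] = []
    for pep in peptides:
        menu.append((pep, 0.0, "", config.base_rate))
    for spec in config.delta_menu:
        for pep in peptides:
            if spec.residue is not None and spec.residue not in pep:
                continue
            loc = ""
            if spec.residue is not None:
                i = pep.index(spec.residue)
                loc = pep[:i] + pep[i].lower() + pep[i + 1 :]
            menu.append((pep, spec.delta, loc, spec.rate))
    return menu


def _condition_rates(
    menu: Sequence[tuple[str, float, str, float]], config: SimConfig
) -> dict[str, list[float]]:
    """Per-condition expected rate for each menu entry."""
    conditions = [c for c, _ in config.conditions]
    rates = {c: [r for _, _, _, r in menu] for c in conditions}
    for diff in config.differential:
        if not 0 <= diff.index < len(menu):
            raise ValueError(f"differential index {diff.index} out of range")
        if diff.condition not in rates:
            raise ValueError(f"differential condition {diff.condition!r} unknown")
        rates[diff.condition][diff.index] *= diff.fold
    return rates


def _random_protein(rng: np.random.Generator, length: int) -> str:
    """Random sequence with regular K sites so it digests into peptides."""
    seq = []
    for i in range(length):
        if i % 12 == 11:
            seq.append("K")
        else:
            seq.append(AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))])
    return "".join(seq)


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Simulate per-sample open-search PSM tables under ``config``.

    Bait peptidoform counts are Poisson(rate x condition effect x sample
    depth factor); emitted delta masses carry sub-bin jitter (+-0.01 Da)
    so rounding is exercised without bin crossings. Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    menu = _build_peptidoform_menu(config)
    rates = _condition_rates(menu, config)

    # prey universe
    prey_entries: list[tuple[str, str, str]] = []
    prey_peptides: list[list[str]] = []
    prey_rates: list[float] = []
    for i in range(config.n_prey_proteins):
        seq = _random_protein(rng, int(rng.integers(150, 400)))
        acc = f"Q{i:05d}"
        gene = f"PREY{i:04d}"
        prey_entries.append((acc, gene, seq))
        peps = tryptic_digest(seq)
        prey_peptides.append(peps if peps else [seq[:10].ljust(7, "A")])
        prey_rates.append(float(rng.lognormal(config.prey_log_mean, config.prey_log_sd)))

    samples: list[SampleInfo] = []
    for cond, n_reps in config.conditions:
        for r in range(1, n_reps + 1):
            samples.append(SampleInfo(sample_id=f"{cond}_{r}", condition=cond,
                                      replicate=r, psm_path=f"{cond}_{r}.psm.tsv"))
    conditions = [c for c, _ in config.conditions]
    comparisons = (
        [(conditions[1], conditions[0])] if len(conditions) >= 2 else []
    )
    design = ExperimentDesign(
        samples=samples,
        bait_gene=config.bait_gene,
        bait_accessions=frozenset({config.bait_accession}),
        comparisons=comparisons,
    )

    records: dict[str, list[PSMRecord]] = {}
    spectrum_counter = 0
    for sample in samples:
        depth = float(rng.lognormal(0.0, config.sample_depth_jitter)) if config.sample_depth_jitter > 0 else 1.0
        sample_records: list[PSMRecord] = []
        for (pep, delta, loc, _), rate in zip(menu, rates[sample.condition]):
            n = int(rng.poisson(rate * depth))
            for _ in range(n):
                jitter = float(rng.uniform(-0.01, 0.01))
                spectrum_counter += 1
                sample_records.append(
                    PSMRecord(
                        peptide=pep,
                        delta_mass=delta + jitter,
                        sample_id=sample.sample_id,
                        spectrum_id=f"spec.{spectrum_counter:07d}",
                        assigned_protein=config.bait_accession,
                        gene=config.bait_gene,
                        localization=loc,
                    )
                )
        for (acc, gene, _), peps, rate in zip(prey_entries, prey_peptides, prey_rates):
            n = int(rng.poisson(rate * depth))
            for _ in range(n):
                pep = peps[int(rng.integers(0, len(peps)))]
                spectrum_counter += 1
                sample_records.append(
                    PSMRecord(
                        peptide=pep,
                        delta_mass=float(rng.uniform(-0.01, 0.01)),
                        sample_id=sample.sample_id,
                        spectrum_id=f"spec.{spectrum_counter:07d}",
                        assigned_protein=acc,
                        gene=gene,
                    )
                )
        records[sample.sample_id] = sample_records

    proteindb = ProteinDB()
    fasta_entries = [(config.bait_accession, config.bait_gene, config.bait_sequence)]
    fasta_entries.extend(prey_entries)
    for acc, gene, seq in fasta_entries:
        proteindb.add(acc, gene, seq)

    truth = [
        TruthEntry(
            peptidoform_key=make_peptidoform_key(menu[d.index][0], menu[d.index][1]).key,
            condition=d.condition,
            fold=d.fold,
        )
        for d in config.differential
        if d.fold != 1.0
    ]
    return SyntheticDataset(
        records=records,
        proteindb=proteindb,
        design=design,
        truth=truth,
        fasta_entries=fasta_entries,
    )


def generate_mutation_scenario(
    config: Optional[SimConfig] = None,
    target_peptide: str = MUTATION_PEPTIDE,
    mutation_delta: float = MUTATION_DELTA,
    swap_fraction: float = 1.0,
    mutant_condition: Optional[str] = None,
) -> SyntheticDataset:
    """Paired mutation scenario: the mutant condition's rate mass moves from
    the unmodified form of ``target_peptide`` to its ``mutation_delta`` form.

    With ``swap_fraction`` 1 the mutant condition emits only the shifted
    form while the control emits only the unmodified one; 0 reduces to the
    null dataset.
    """
    if not 0.0 <= swap_fraction <= 1.0:
        raise ValueError("swap_fraction must be in [0, 1]")
    config = config or SimConfig()
    if target_peptide not in config.bait_sequence:
        raise ValueError(
            f"bait sequence does not contain target peptide {target_peptide!r}"
        )
    if mutant_condition is None:
        mutant_condition = config.conditions[-1][0]
    control_conditions = [c for c, _ in config.conditions if c != mutant_condition]

    menu = _build_peptidoform_menu(config)
    peptides = [m[0] for m in menu]
    if target_peptide not in peptides:
        raise ValueError(
            f"target peptide {target_peptide!r} not in the simulated peptide set; "
            "increase n_bait_peptides"
        )
    unmod_index = next(
        i for i, (pep, delta, _, _) in enumerate(menu)
        if pep == target_peptide and delta == 0.0
    )
    # append the mutated form; it inherits the unmodified rate scaled by the swap
    loc_index = target_peptide.index("G") if "G" in target_peptide else 0
    localization = (
        target_peptide[:loc_index]
        + target_peptide[loc_index].lower()
        + target_peptide[loc_index + 1 :]
    )
    base = config.base_rate
    mutated_spec = DeltaSpec(mutation_delta, None, base * swap_fraction)

    cfg = copy.deepcopy(config)
    cfg.delta_menu = list(cfg.delta_menu) + [mutated_spec]
    # DeltaSpec applies menu-wide; differential folds confine the mutated form
    # to the target peptide in the mutant condition and shift the unmodified
    # form's rate mass there by the swap fraction.
    menu2 = _build_peptidoform_menu(cfg)
    diffs: list[DifferentialSpec] = []
    eps = 1e-9
    for i, (pep, delta, _, rate) in enumerate(menu2):
        if delta == mutation_delta and pep != target_peptide:
            # off-target copies of the mutated form: suppress everywhere
            for cond, _ in cfg.conditions:
                diffs.append(DifferentialSpec(i, eps, cond))
        elif delta == mutation_delta and pep == target_peptide:
            for cond in control_conditions:
                diffs.append(DifferentialSpec(i, eps, cond))
        elif i == unmod_index and swap_fraction > 0:
            remaining = max(1.0 - swap_fraction, eps)
            diffs.append(DifferentialSpec(i, remaining, mutant_condition))
    cfg.differential = list(cfg.differential) + diffs
    dataset = generate_dataset(cfg)

    if swap_fraction == 0:
        dataset.truth = []
    else:
        mutated_key = make_peptidoform_key(target_peptide, mutation_delta).key
        unmod_key = make_peptidoform_key(target_peptide, 0.0).key
        dataset.truth = [
            TruthEntry(mutated_key, mutant_condition, float("inf")),
            TruthEntry(unmod_key, mutant_condition, max(1.0 - swap_fraction, eps)),
        ]
        # attach the localization string to emitted mutated-form PSMs
        for sample_records in dataset.records.values():
            for i, rec in enumerate(sample_records):
                if rec.peptide == target_peptide and abs(rec.delta_mass - mutation_delta) < 0.05:
                    sample_records[i] = PSMRecord(
                        **{**rec.__dict__, "localization": localization}
                    )
    return dataset


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write psm.tsv per sample, the FASTA, and a YAML design manifest.

    Returns the manifest path; the files round-trip through the package
    readers losslessly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sample in dataset.design.samples:
        write_psm_table(out_dir / sample.psm_path, dataset.records[sample.sample_id])
    write_fasta(out_dir / "proteins.fasta", dataset.fasta_entries)
    manifest = {
        "bait_gene": dataset.design.bait_gene,
        "bait_accessions": sorted(dataset.design.bait_accessions),
        "comparisons": [list(c) for c in dataset.design.comparisons],
        "samples": [
            {
                "sample_id": s.sample_id,
                "psm_path": s.psm_path,
                "condition": s.condition,
                "replicate": s.replicate,
            }
            for s in dataset.design.samples
        ],
    }
    manifest_path = out_dir / "design.yaml"
    with open(manifest_path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("peptidoform\tcondition\tfold\n")
        for t in dataset.truth:
            fh.write(f"{t.peptidoform_key}\t{t.condition}\t{t.fold}\n")
    return manifest_path
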