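import pandas as pd
import pytest

from baitform.io_formats import ExperimentDesign, SampleInfo
from baitform.peptidoform import CountMatrix, make_peptidoform_key

PSM_HEADER = (
    "Spectrum\tPeptide\tModified Peptide\tDelta Mass\tProtein\tGene\t"
    "Mapped Proteins\tMSFragger Localization\tObserved Modifications\tIntensity"
)


def psm_row(peptide, delta, protein="P01112", gene="HRAS", spectrum="s.1",
            modified="", mapped="", localization="", observed="", intensity=""):
    return "\t".join(
        [spectrum, peptide, modified, str(delta), protein, gene,
         mapped, localization, observed, intensity]
    )


@pytest.fixture
def write_psm_file(tmp_path):
    counter = iter(range(10000))

    def _write(rows, name=None):
        name = name or f"psm_{next(counter)}.tsv"
        path = tmp_path / name
        path.write_text(PSM_HEADER + "\n" + "".join(r + "\n" for r in rows))
        return path

    return _write


@pytest.fixture
def design_2v2():
    return ExperimentDesign(
        samples=[
            SampleInfo("t1", "test", 1),
            SampleInfo("t2", "test", 2),
            SampleInfo("c1", "ctrl", 1),
            SampleInfo("c2", "ctrl", 2),
        ],
        bait_gene="HRAS",
        bait_accessions=frozenset({"P01112"}),
        comparisons=[("test", "ctrl")],
    )


def matrix_from_rows(rows, samples, scope="bait", normalized=False):
    """Build a CountMatrix from {(peptide, delta): [counts per sample]}."""
    forms = {}
    data = {}
    for (pep, delta), counts in rows.items():
        pf = make_peptidoform_key(pep, delta)
        forms[pf.key] = pf
        data[pf.key] = counts
    df = pd.DataFrame.from_dict(data, orient="index", columns=samples, dtype=float)
    return CountMatrix(df=df, peptidoforms=forms, scope=scope, normalized=normalized)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(entries, name="db.fasta"):
        path = tmp_path / name
        lines = []
        for header, seq in entries:
            lines.append(">" + header)
            lines.append(seq)
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
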