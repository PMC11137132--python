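"""Normalization, filtering and differential scoring of bait peptidoforms.

Counts are normalized to the comparison sample with the fewest bait PSMs,
peptidoforms with a single PSM in the whole dataset are excluded, and
differential presence is scored per comparison with a probability (AvgP)
and a Bayesian FDR — either through an external SAINTexpress binary or an
internal two-component Poisson surrogate with the same output shape.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .io_formats import ExperimentDesign, write_saint_inputs
from .peptidoform import CountMatrix, Peptidoform

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_PRIOR = 0.5
DEFAULT_BFDR_THRESHOLD = 0.05


@dataclass(frozen=True)
class DifferentialResult:
    peptidoform: Peptidoform
    test_condition: str
    control_condition: str
    avgp: float
    log2fc: float
    mean_test: float
    mean_control: float
    bfdr: Optional[float] = None
    significant: bool = False


def normalize_bait_counts(
    counts: CountMatrix, samples: Optional[Sequence[str]] = None
) -> CountMatrix:
    """Scale each sample's counts to the smallest per-sample total.

    Restricted to ``samples`` (default: all columns). Each column is
    multiplied by min_total/total so every total equals the comparison
    minimum; the minimum-total sample is unchanged and within-sample
    proportions are preserved.
    """
    if samples is None:
        samples = counts.sample_ids
    totals = {s: counts.total(s) for s in samples}
    zero = [s for s, t in totals.items() if t == 0]
    if zero:
        raise ValueError(
            f"cannot normalize: zero bait PSMs in sample(s) {zero} — comparison impossible"
        )
    min_total = min(totals.values())
    df = counts.df[list(samples)].copy()
    for s in samples:
        df[s] = df[s] * (min_total / totals[s])
    return CountMatrix(
        df=df,
        peptidoforms=dict(counts.peptidoforms),
        scope=counts.scope,
        normalized=True,
    )


def filter_singletons(counts: CountMatrix) -> CountMatrix:
    """Drop peptidoforms with exactly one PSM across the whole dataset.

    Must run on raw counts, before normalization.
    """
    if counts.normalized:
        raise ValueError("singleton filter must run on raw, pre-normalization counts")
    totals = counts.row_totals()
    keep = totals[totals != 1].index.tolist()
    dropped = [k for k in counts.keys if k not in set(keep)]
    if dropped:
        logger.info("singleton filter removed %d peptidoform(s): %s", len(dropped), dropped)
    if not keep:
        logger.warning("singleton filter removed every peptidoform")
    return counts.subset_rows(keep)


def _log_poisson_density(t: np.ndarray, lam: float) -> np.ndarray:
    """Continuous Poisson log-density: t*log(lam) - lam - lgamma(t+1).

    Extends the Poisson pmf to fractional counts (post-normalization)
    via the gamma-function factorial.
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(t > 0, t * math.log(lam), 0.0)
    return term - lam - gammaln(t + 1.0)


def score_internal(
    counts: CountMatrix,
    design: ExperimentDesign,
    comparison: tuple[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    prior: float = DEFAULT_PRIOR,
) -> list[DifferentialResult]:
    """Surrogate scorer: two-component Poisson per peptidoform.

    For peptidoform i, the control rate is lam0 = mean control count + a
    and the enriched rate lam1 = max(mean test count + a, lam0); each test
    replicate's probability of arising from the enriched component is
    p_k = pi*f(t_k|lam1) / (pi*f(t_k|lam1) + (1-pi)*f(t_k|lam0)) with f
    the continuous Poisson density, and AvgP is the replicate mean. The
    construction forces AvgP = pi exactly when the test mean does not
    exceed the control mean, so depletion is only ever discovered by
    scoring the reversed comparison.
    """
    test, control = comparison
    test_samples = design.samples_in(test)
    control_samples = design.samples_in(control)
    if not test_samples:
        raise ValueError(f"comparison has no test replicates for condition {test!r}")
    if not control_samples:
        raise ValueError(f"comparison has no control replicates for condition {control!r}")
    a = pseudocount
    results: list[DifferentialResult] = []
    for key in counts.keys:
        t_counts = counts.df.loc[key, test_samples].to_numpy(dtype=float)
        c_counts = counts.df.loc[key, control_samples].to_numpy(dtype=float)
        mean_test = float(t_counts.mean())
        mean_control = float(c_counts.mean())
        lam0 = mean_control + a
        lam1 = max(mean_test + a, lam0)
        if lam1 == lam0:
            p = np.full_like(t_counts, prior)
        else:
            log_f1 = _log_poisson_density(t_counts, lam1) + math.log(prior)
            log_f0 = _log_poisson_density(t_counts, lam0) + math.log(1.0 - prior)
            m = np.maximum(log_f1, log_f0)
            p = np.exp(log_f1 - m) / (np.exp(log_f1 - m) + np.exp(log_f0 - m))
        results.append(
            DifferentialResult(
                peptidoform=counts.peptidoforms[key],
                test_condition=test,
                control_condition=control,
                avgp=float(p.mean()),
                log2fc=math.log2((mean_test + a) / (mean_control + a)),
                mean_test=mean_test,
                mean_control=mean_control,
            )
        )
    return results


def compute_bfdr(results: Sequence[DifferentialResult]) -> list[DifferentialResult]:
    """Bayesian FDR: cumulative mean of (1 - AvgP) down the AvgP-descending
    ranking; tied AvgP values share the larger rank's value."""
    if not results:
        return []
    for r in results:
        if not 0.0 <= r.avgp <= 1.0:
            raise ValueError(f"AvgP out of [0,1]: {r.avgp}")
    order = sorted(range(len(results)), key=lambda i: -results[i].avgp)
    sorted_avgp = [results[order[i]].avgp for i in range(len(order))]
    cum = np.cumsum([1.0 - p for p in sorted_avgp])
    bfdr = cum / np.arange(1, len(order) + 1)
    # ties share the value at the last (largest) rank of the tie group
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and sorted_avgp[j + 1] == sorted_avgp[i]:
            j += 1
        bfdr[i : j + 1] = bfdr[j]
        i = j + 1
    out: list[DifferentialResult] = list(results)
    for rank, idx in enumerate(order):
        out[idx] = replace(results[idx], bfdr=float(bfdr[rank]))
    return out


def call_significant(
    results: Sequence[DifferentialResult],
    threshold: float = DEFAULT_BFDR_THRESHOLD,
) -> list[DifferentialResult]:
    """Mark results with BFDR strictly below ``threshold`` significant."""
    out = []
    for r in results:
        if r.bfdr is None:
            raise ValueError("BFDR not populated; run compute_bfdr first")
        out.append(replace(r, significant=r.bfdr < threshold))
    return out


def score_comparison(
    raw_counts: CountMatrix,
    design: ExperimentDesign,
    comparison: tuple[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    prior: float = DEFAULT_PRIOR,
    bfdr_threshold: float = DEFAULT_BFDR_THRESHOLD,
    both_directions: bool = True,
) -> list[DifferentialResult]:
    """Full per-comparison scoring with the internal surrogate.

    Order is fixed: singleton filter on raw counts, then normalization
    restricted to the comparison samples, then scoring. With
    ``both_directions`` the comparison is also scored with test and
    control swapped so depletion is reported symmetrically; BFDR is
    computed within each direction.
    """
    test, control = comparison
    samples = design.samples_in(test) + design.samples_in(control)
    filtered = filter_singletons(raw_counts)
    norm = normalize_bait_counts(filtered, samples)
    directions = [(test, control)]
    if both_directions:
        directions.append((control, test))
    results: list[DifferentialResult] = []
    for direction in directions:
        scored = score_internal(norm, design, direction, pseudocount, prior)
        results.extend(call_significant(compute_bfdr(scored), bfdr_threshold))
    return results


class SaintExpressError(RuntimeError):
    """Raised when the external SAINTexpress binary fails."""


def run_saintexpress(
    counts: CountMatrix,
    design: ExperimentDesign,
    comparison: tuple[str, str],
    binary: str = "SAINTexpress-spc",
    options: str = "",
    workdir: Optional[str | Path] = None,
) -> Path:
    """Run the external SAINTexpress spectral-count binary on one comparison.

    Writes the interaction/prey/bait triple into a workspace, invokes the
    binary there, and returns the path of the ``list.txt`` output.
    Options are passed through verbatim. Raises FileNotFoundError when
    the binary is absent (callers may fall back to the internal scorer)
    and SaintExpressError on a nonzero exit.
    """
    resolved = shutil.which(binary)
    if resolved is None:
        raise FileNotFoundError(
            f"SAINTexpress binary {binary!r} not found on PATH"
        )
    workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="saint_"))
    inter, prey, bait = write_saint_inputs(counts, design, comparison, workdir)
    cmd = [resolved, *options.split(), inter.name, prey.name, bait.name]
    proc = subprocess.run(
        cmd, cwd=workdir, capture_output=True, text=True, check=False
    )
    if proc.returncode != 0:
        raise SaintExpressError(
            f"SAINTexpress exited with {proc.returncode}: {proc.stderr.strip()}"
        )
    out = workdir / "list.txt"
    if not out.exists():
        raise SaintExpressError(f"SAINTexpress produced no list.txt in {workdir}")
    return out
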