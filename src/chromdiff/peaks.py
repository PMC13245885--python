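"""FDR-controlled differential peak calling and pattern classification.

Window-level posterior probabilities of the differential HMM state are
thresholded by controlling the total FDR

    sum_j (1 - rho_j2) I(rho_j2 >= 1 - alpha) / sum_j I(rho_j2 >= 1 - alpha),

the posterior-expected proportion of false calls among called windows.
Contiguous called windows merge into peaks; each peak is labelled with its
winning combinatorial enrichment pattern via the average mixture posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import GenomicWindows
from .emissions import PatternDesign
from .hmm import DIFFERENTIAL, FitResult, PosteriorSet, viterbi, _emission_logliks

__all__ = [
    "FDRDecision",
    "PeakSet",
    "fdr_cutoff",
    "call_peaks",
    "classify_peaks",
    "write_peaks",
    "write_track",
    "read_peaks",
]


@dataclass(frozen=True)
class FDRDecision:
    """Outcome of total-FDR control: the posterior cutoff alpha, the level
    requested, the realized estimate and the number of windows called."""

    alpha_cutoff: float
    nominal_level: float
    estimated_fdr: float
    n_called: int
    called: np.ndarray  # boolean mask over windows


def fdr_cutoff(rho2: np.ndarray, nominal: float = 0.05) -> FDRDecision:
    """Choose the posterior cutoff controlling the total FDR at `nominal`.

    Windows are ranked by rho2 descending; the call set is the largest
    prefix whose mean posterior error (1 - rho2) stays at or below the
    nominal level.  Windows tied with the boundary value are included only
    if the constraint still holds with all of them, otherwise all are
    excluded (deterministic).
    """
    if not (0.0 < nominal < 1.0):
        raise ValueError("nominal FDR must be in (0, 1)")
    rho2 = np.asarray(rho2, dtype=np.float64)
    if np.any(rho2 < 0) or np.any(rho2 > 1):
        raise ValueError("rho2 must lie in [0, 1]")
    M = len(rho2)
    order = np.argsort(-rho2, kind="stable")
    sorted_rho = rho2[order]
    cum_fdr = np.cumsum(1.0 - sorted_rho) / np.arange(1, M + 1)
    ok = np.flatnonzero(cum_fdr <= nominal)
    k = 0 if len(ok) == 0 else int(ok[-1]) + 1
    if 0 < k < M:
        boundary = sorted_rho[k - 1]
        k_ext = int(np.searchsorted(-sorted_rho, -boundary, side="right"))
        if k_ext > k:
            k = k_ext if cum_fdr[k_ext - 1] <= nominal else int(
                np.searchsorted(-sorted_rho, -boundary, side="left")
            )
    called = np.zeros(M, dtype=bool)
    called[order[:k]] = True
    est = float(cum_fdr[k - 1]) if k > 0 else 0.0
    alpha = float(1.0 - sorted_rho[k - 1]) if k > 0 else float("nan")
    return FDRDecision(
        alpha_cutoff=alpha, nominal_level=nominal, estimated_fdr=est, n_called=k, called=called
    )


@dataclass
class PeakSet:
    """Merged differential intervals with pattern labels.

    One row per peak: coordinates, number of member windows, mean and max of
    the differential-state posterior, the winning pattern set and its
    average mixture posterior.
    """

    table: pd.DataFrame
    design: PatternDesign | None = None

    def __len__(self) -> int:
        return len(self.table)


def _merge_runs(called: np.ndarray, windows: GenomicWindows) -> list[np.ndarray]:
    """Group indices of called windows into genomically contiguous runs."""
    idx = np.flatnonzero(called)
    if len(idx) == 0:
        return []
    adj = windows.adjacency()
    runs, current = [], [idx[0]]
    for prev, j in zip(idx[:-1], idx[1:]):
        if j == prev + 1 and adj[prev]:
            current.append(j)
        else:
            runs.append(np.asarray(current))
            current = [j]
    runs.append(np.asarray(current))
    return runs


def call_peaks(
    fit: FitResult,
    windows: GenomicWindows,
    nominal: float = 0.05,
    mode: str = "fdr",
) -> PeakSet:
    """Call differential peaks from a converged fit.

    mode="fdr" merges genomically contiguous windows that pass the total-FDR
    cutoff.  mode="viterbi-extend" additionally extends each passing window
    through the contiguous run of windows whose Viterbi state is
    differential, then merges.  Peaks never span chromosome boundaries or
    gaps in the window grid.
    """
    rho2 = fit.posteriors.rho[:, DIFFERENTIAL]
    if len(rho2) != len(windows):
        raise ValueError("fit and windows length mismatch")
    decision = fdr_cutoff(rho2, nominal)
    called = decision.called.copy()
    if mode == "viterbi-extend":
        # recompute the Viterbi path from the fitted model
        from .hmm import ChainParameters  # noqa: F401  (doc aid)

        path = fit.viterbi_path if hasattr(fit, "viterbi_path") else None
        if path is None:
            raise ValueError("viterbi-extend requires fit.viterbi_path; use call_peaks_dataset")
        called = _extend_through_state(called, path == DIFFERENTIAL, windows)
    elif mode != "fdr":
        raise ValueError(f"unknown mode {mode!r}")
    return _build_peakset(called, fit, windows, decision)


def call_peaks_dataset(
    dataset,
    fit: FitResult,
    nominal: float = 0.05,
    mode: str = "fdr",
) -> PeakSet:
    """Like :func:`call_peaks` but computes the Viterbi path when needed."""
    if mode == "viterbi-extend":
        emis, _ = _emission_logliks(dataset, fit.params)
        fit.viterbi_path = viterbi(emis, fit.params.chain)
    return call_peaks(fit, dataset.windows, nominal=nominal, mode=mode)


def _extend_through_state(
    called: np.ndarray, differential: np.ndarray, windows: GenomicWindows
) -> np.ndarray:
    """Extend called windows through contiguous differential-Viterbi runs."""
    out = called.copy()
    adj = windows.adjacency()
    for run in _runs_of(differential, adj):
        if called[run].any():
            out[run] = True
    return out


def _runs_of(mask: np.ndarray, adj: np.ndarray) -> list[np.ndarray]:
    runs, current = [], []
    for j, on in enumerate(mask):
        if on and (not current or (current[-1] == j - 1 and adj[j - 1])):
            current.append(j)
        elif on:
            runs.append(np.asarray(current))
            current = [j]
        elif current:
            runs.append(np.asarray(current))
            current = []
    if current:
        runs.append(np.asarray(current))
    return runs


def _build_peakset(
    called: np.ndarray, fit: FitResult, windows: GenomicWindows, decision: FDRDecision
) -> PeakSet:
    rho2 = fit.posteriors.rho[:, DIFFERENTIAL]
    rows = []
    for run in _merge_runs(called, windows):
        rows.append(
            {
                "chrom": windows.chrom[run[0]],
                "start": int(windows.start[run[0]]),
                "end": int(windows.end[run[-1]]),
                "n_windows": len(run),
                "mean_rho2": float(rho2[run].mean()),
                "max_rho2": float(rho2[run].max()),
                "_windows": run,
            }
        )
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_windows", "mean_rho2", "max_rho2", "_windows"]
    )
    peaks = PeakSet(table=table, design=fit.params.design)
    peaks.decision = decision
    return classify_peaks(peaks, fit.posteriors, fit.params.design)


def classify_peaks(
    peaks: PeakSet, posteriors: PosteriorSet, design: PatternDesign
) -> PeakSet:
    """Label each peak with its winning combinatorial pattern.

    The mixture posteriors w of the member windows are averaged; the label
    is the argmax component (ties go to the lower canonical index).
    """
    if posteriors.w is None:
        raise ValueError("posteriors must carry mixture posteriors w")
    labels = design.labels()
    names, probs = [], []
    for run in peaks.table["_windows"]:
        run = np.asarray(run)
        if len(run) == 0:
            raise ValueError("empty peak")
        avg = posteriors.w[run].mean(axis=0)
        # ties (within rounding) break toward the lower canonical index
        best = int(np.flatnonzero(avg >= avg.max() - 1e-9)[0])
        names.append(labels[best])
        probs.append(float(avg[best]))
    peaks.table["pattern"] = names
    peaks.table["pattern_posterior"] = probs
    return peaks


# ---------------------------------------------------------------------------
# output writers (BED6 / bedGraph, 0-based half-open)

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_peaks(peaks: PeakSet, path: str | Path, table_path: str | Path | None = None) -> None:
    """BED6 peaks (name = pattern, score = round(1000 * pattern posterior))
    plus an optional full TSV table."""
    df = peaks.table
    bed = pd.DataFrame(
        {
            "chrom": df.get("chrom", pd.Series(dtype=object)),
            "start": df.get("start", pd.Series(dtype=int)),
            "end": df.get("end", pd.Series(dtype=int)),
            "name": df.get("pattern", pd.Series(dtype=object)),
            "score": (1000.0 * df.get("pattern_posterior", pd.Series(dtype=float))).round().astype("Int64"),
            "strand": ["."] * len(df),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
    if table_path is not None:
        df.drop(columns=["_windows"]).to_csv(table_path, sep="\t", index=False)


def read_peaks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLS, dtype={"name": str})
    if len(df) == 0:
        return pd.DataFrame(columns=_BED_COLS)
    if len(df) and (df["score"].min() < 0 or df["score"].max() > 1000):
        raise ValueError("BED scores must lie in [0, 1000]")
    return df


def write_track(rho2: np.ndarray, windows: GenomicWindows, path: str | Path) -> None:
    """bedGraph track of the differential-state posterior probability."""
    pd.DataFrame(
        {
            "chrom": windows.chrom,
            "start": windows.start,
            "end": windows.end,
            "value": np.asarray(rho2, dtype=np.float64),
        }
    ).to_csv(path, sep="\t", index=False, header=False)
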