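"""Spike-in QC, cell filtering, normalization, coverage, and transforms.

Accuracy: per cell, the Pearson correlation between log10(UMI + 1) and
log10(expected molecules + 1) over the spike-in species actually detected
(UMI > 0) in that cell. Sensitivity: per species, the percent of wells
detecting it, fitted against log10 molecules with an asymmetric
five-parameter logistic (5PL); EC50 is the molecule count at the 50%
detection crossing of the fitted curve.

Cell filtering applies a hard floor of 250 detected genes, then
3-MAD outlier rules (low tail for UMIs, genes and accuracy; high tail for
spike-in percentage) on the cells passing the hard filter. Normalization is
the standard log1p of counts scaled to 10,000 per cell, with spike-in rows
excluded from both the totals and the output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .quantify import CountMatrix
from .reference import TranscriptRecord

HARD_MIN_GENES = 250
MAD_K = 3.0
#: consistency constant making the MAD comparable to a standard deviation
MAD_SCALE = 1.4826
NORM_SCALE_FACTOR = 1e4
MIN_DETECTED_FOR_ACCURACY = 3


class QcError(ValueError):
    pass


# ---------------------------------------------------------------------------
# spike-in accuracy
# ---------------------------------------------------------------------------


def ercc_accuracy(
    spike_counts: Mapping[str, float], expected: Mapping[str, float]
) -> float | None:
    """Pearson r of log10(UMI+1) vs log10(expected molecules+1).

    Restricted to species detected in the cell (UMI > 0); returns None with
    fewer than 3 detected species or zero variance in either vector.
    """
    missing = set(spike_counts) - set(expected)
    if missing:
        raise QcError(f"species missing from expected table: {sorted(missing)}")
    detected = [s for s, n in spike_counts.items() if n > 0]
    if len(detected) < MIN_DETECTED_FOR_ACCURACY:
        return None
    x = np.log10(np.array([spike_counts[s] for s in detected]) + 1.0)
    y = np.log10(np.array([expected[s] for s in detected]) + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# sensitivity (5PL detection curve)
# ---------------------------------------------------------------------------


def five_pl(m: np.ndarray, p_min: float, p_max: float, h: float, s: float,
            m_ref: float) -> np.ndarray:
    """Asymmetric five-parameter logistic on molecule count m."""
    m = np.asarray(m, dtype=float)
    # evaluate (m_ref/m)**h in log space so extreme ratios cannot overflow
    with np.errstate(divide="ignore"):
        log_ratio = h * (np.log(m_ref) - np.log(m))
    return p_min + (p_max - p_min) * np.exp(-s * np.logaddexp(0.0, log_ratio))


@dataclass
class SensitivityFit:
    species: pd.DataFrame  # species_id, expected_molecules, detection_pct
    p_min: float
    p_max: float
    h: float
    s: float
    m_ref: float
    ec50: float | None
    ec50_reliable: bool

    def predict(self, m) -> np.ndarray:
        return five_pl(np.asarray(m, dtype=float), self.p_min, self.p_max,
                       self.h, self.s, self.m_ref)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "p_min": self.p_min, "p_max": self.p_max, "h": self.h,
            "s": self.s, "m_ref": self.m_ref, "ec50": self.ec50,
            "ec50_reliable": self.ec50_reliable,
            "species": self.species.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def fit_detection_curve(
    molecules: np.ndarray, detection_pct: np.ndarray,
    species_ids: Sequence[str] | None = None,
) -> SensitivityFit:
    """Fit the 5PL to (molecules, percent-of-wells-detected) points."""
    m = np.asarray(molecules, dtype=float)
    y = np.asarray(detection_pct, dtype=float)
    keep = m > 0
    m, y = m[keep], y[keep]
    if species_ids is None:
        species_ids = [f"s{i}" for i in range(len(m))]
    else:
        species_ids = [s for s, k in zip(species_ids, keep) if k]
    if len(m) < 5:
        raise QcError("need at least 5 positive-molecule species to fit")

    m_ref0 = float(m[np.argmin(np.abs(y - 50.0))])
    p0 = [0.0, 100.0, 1.0, 1.0, max(m_ref0, 1e-6)]
    lower = [0.0, 0.0, 1e-3, 1e-3, float(m.min()) * 1e-3]
    upper = [100.0, 100.0, 50.0, 50.0, float(m.max()) * 1e3]

    def resid(params):
        return five_pl(m, *params) - y

    sol = optimize.least_squares(resid, p0, bounds=(lower, upper))
    p_min, p_max, h, s, m_ref = (float(v) for v in sol.x)

    # EC50: bisection of the fitted curve on the observed molecule range
    lo, hi = float(m.min()), float(m.max())
    f = lambda mm: five_pl(np.array([mm]), p_min, p_max, h, s, m_ref)[0] - 50.0
    ec50 = None
    reliable = False
    if f(lo) < 0 < f(hi):
        a, b = lo, hi
        for _ in range(200):
            mid = math.sqrt(a * b)  # bisect in log space
            if f(mid) < 0:
                a = mid
            else:
                b = mid
        ec50 = math.sqrt(a * b)
        reliable = True
    table = pd.DataFrame(
        {"species_id": species_ids, "expected_molecules": m, "detection_pct": y}
    )
    return SensitivityFit(table, p_min, p_max, h, s, m_ref, ec50, reliable)


def sensitivity_curve(
    matrix: CountMatrix, expected: Mapping[str, float]
) -> SensitivityFit:
    """Per-species detection rate over wells, then the 5PL fit.

    ``expected`` maps spike-in species ids (which must be matrix rows) to
    expected molecules per well.
    """
    if len(matrix.cells) < 2:
        raise QcError("need at least 2 wells to estimate detection rates")
    ids = [s for s in expected if s in set(matrix.genes)]
    if not ids:
        raise QcError("no spike-in rows present in the matrix")
    sub = matrix.matrix.loc[ids, :]
    y = 100.0 * (sub.values > 0).mean(axis=1)
    m = np.array([expected[s] for s in ids], dtype=float)
    return fit_detection_curve(m, y, ids)


# ---------------------------------------------------------------------------
# gene body coverage
# ---------------------------------------------------------------------------

N_COVERAGE_BINS = 100


def gene_body_coverage(
    alignments: Iterable[tuple[str, int, int]],
    transcripts: Sequence[TranscriptRecord],
) -> np.ndarray:
    """Normalized 5'->3' percentile coverage profile (100 bins, max = 1).

    ``alignments`` are (transcript_id, start, end) in sense coordinates.
    Transcripts shorter than 100 nt are skipped.
    """
    lengths = {t.transcript_id: t.length for t in transcripts}
    bins = np.zeros(N_COVERAGE_BINS, dtype=float)
    for tid, start, end in alignments:
        L = lengths.get(tid)
        if L is None or L < N_COVERAGE_BINS:
            continue
        start = max(0, start)
        end = min(L, end)
        if end <= start:
            continue
        b0 = int(start * N_COVERAGE_BINS / L)
        b1 = int(math.ceil(end * N_COVERAGE_BINS / L))
        bins[b0:b1] += 1.0
    peak = bins.max()
    if peak > 0:
        bins = bins / peak
    return bins


def locate_reads(
    reads: Iterable, transcripts: Sequence[TranscriptRecord], k: int = 21
) -> list[tuple[str, int, int]]:
    """Approximate sense alignments of antisense reads by exact k-mer seeding.

    Each read is reverse-complemented; the first of its k-mers that occurs
    uniquely in the transcript set anchors the read. Reads with no unique
    seed are skipped. Good enough for coverage profiling at low error rates.
    """
    from .reference import revcomp

    seed_map: dict[str, tuple[str, int] | None] = {}
    for t in transcripts:
        for i in range(len(t.sequence) - k + 1):
            km = t.sequence[i : i + k]
            if km in seed_map:
                seed_map[km] = None  # non-unique
            else:
                seed_map[km] = (t.transcript_id, i)
    out: list[tuple[str, int, int]] = []
    for r in reads:
        seq = r.sequence if hasattr(r, "sequence") else r
        sense = revcomp(seq)
        for i in range(len(sense) - k + 1):
            hit = seed_map.get(sense[i : i + k])
            if hit is not None:
                tid, pos = hit
                start = pos - i
                out.append((tid, start, start + len(sense)))
                break
    return out


# ---------------------------------------------------------------------------
# per-cell metrics and filtering
# ---------------------------------------------------------------------------


@dataclass
class CellQcMetrics:
    cell_id: str
    total_umis: int
    genes_detected: int
    spikein_pct: float
    accuracy_r: float | None


def compute_cell_metrics(
    matrix: CountMatrix,
    spikein_ids: Sequence[str],
    expected: Mapping[str, float],
) -> pd.DataFrame:
    """One row per cell: totals, genes detected, spike-in %, accuracy."""
    unknown = set(spikein_ids) - set(matrix.genes)
    if unknown:
        raise QcError(f"unknown spike-in ids: {sorted(unknown)}")
    spike_ids = list(spikein_ids)
    bio_genes = [g for g in matrix.genes if g not in set(spike_ids)]
    rows = []
    for cell in matrix.cells:
        col = matrix.matrix[cell]
        total = int(col.sum())
        genes_detected = int((col[bio_genes] > 0).sum())
        spike_total = int(col[spike_ids].sum())
        spikein_pct = 100.0 * spike_total / total if total else 0.0
        acc = ercc_accuracy(
            {s: int(col[s]) for s in spike_ids}, expected
        )
        rows.append(
            {
                "cell_id": cell,
                "total_umis": total,
                "genes_detected": genes_detected,
                "spikein_pct": spikein_pct,
                "accuracy_r": acc if acc is not None else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def _mad(values: np.ndarray) -> float:
    med = np.median(values)
    return MAD_SCALE * float(np.median(np.abs(values - med)))


#: metrics filtered on the low tail (quality drops when these fall)
LOW_TAIL_METRICS = ("total_umis", "genes_detected", "accuracy_r")
#: metrics filtered on the high tail (quality drops when these rise)
HIGH_TAIL_METRICS = ("spikein_pct",)


def filter_cells(
    metrics: pd.DataFrame,
    min_genes: int = HARD_MIN_GENES,
    n_mads: float = MAD_K,
    mad_scale: float = MAD_SCALE,
) -> pd.DataFrame:
    """Keep/drop decision per cell with accumulated reasons.

    A cell is dropped if it detects fewer than ``min_genes`` genes (hard
    filter), or any low-tail metric falls below median - n_mads*MAD, or any
    high-tail metric rises above median + n_mads*MAD. Median/MAD statistics
    are computed over cells passing the hard filter only.
    """
    if metrics.empty:
        raise QcError("no cells to filter")
    out = metrics.copy()
    out["keep"] = True
    out["reasons"] = [[] for _ in range(len(out))]

    hard_fail = out["genes_detected"] < min_genes
    for cell in out.index[hard_fail]:
        out.at[cell, "keep"] = False
        out.at[cell, "reasons"].append("low_genes_hard")

    eligible = out.loc[~hard_fail]

    def mad_of(col: pd.Series) -> tuple[float, float]:
        vals = col.dropna().values.astype(float)
        if len(vals) == 0:
            return math.nan, math.nan
        med = float(np.median(vals))
        mad = mad_scale * float(np.median(np.abs(vals - med)))
        return med, mad

    for metric in LOW_TAIL_METRICS:
        med, mad = mad_of(eligible[metric])
        if math.isnan(med):
            continue
        cut = med - n_mads * mad
        for cell in eligible.index:
            v = out.at[cell, metric]
            if pd.notna(v) and v < cut:
                out.at[cell, "keep"] = False
                out.at[cell, "reasons"].append(f"low_{metric}")
    for metric in HIGH_TAIL_METRICS:
        med, mad = mad_of(eligible[metric])
        if math.isnan(med):
            continue
        cut = med + n_mads * mad
        for cell in eligible.index:
            v = out.at[cell, metric]
            if pd.notna(v) and v > cut:
                out.at[cell, "keep"] = False
                out.at[cell, "reasons"].append(f"high_{metric}")
    out["reasons"] = [",".join(r) for r in out["reasons"]]
    return out


# ---------------------------------------------------------------------------
# normalization and transforms
# ---------------------------------------------------------------------------


def normalize_matrix(
    matrix: CountMatrix, spikein_ids: Sequence[str] = ()
) -> pd.DataFrame:
    """ln(1 + 1e4 * count / cell_total) per biological gene.

    Spike-in rows are excluded from the per-cell totals and from the output
    so spike content does not deflate biological expression.
    """
    bio = [g for g in matrix.genes if g not in set(spikein_ids)]
    counts = matrix.matrix.loc[bio, :].astype(float)
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise QcError(f"zero-total cells (filter first): {list(zero.index)}")
    return np.log1p(NORM_SCALE_FACTOR * counts / totals)


def asinh_transform(x):
    """Hyperbolic arcsine, the standard display transform for index-sort
    fluorescence values (monotone, odd, ~linear near 0, ~log for large x)."""
    return np.arcsinh(x)


def qc_report_tsv(path: str | Path, filtered: pd.DataFrame) -> None:
    filtered.to_csv(path, sep="\t")


def coverage_profile_tsv(path: str | Path, bins: np.ndarray) -> None:
    pd.DataFrame(
        {"bin": np.arange(1, len(bins) + 1), "normalized_coverage": bins}
    ).to_csv(path, sep="\t", index=False)
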