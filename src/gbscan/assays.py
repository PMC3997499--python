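"""Assay-side analytics: melting temperatures from thermal-shift curves,
SEC molecular-weight calibration, and sequence-derived properties.

Tm is defined as the midpoint of the thermal unfolding transition.  The
primary estimator locates the maximum of the smoothed derivative of the
fluorescence signal (the convention of plate-reader software); a Boltzmann
sigmoid fit is provided as a cross-check.  SEC calibration is the standard
log-linear fit of log10(MW) against elution volume over protein standards.
Sequence properties (average-mass MW, A280 extinction, pairwise global
alignment identity/similarity) follow the common ProtParam/BLOSUM62
conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress
from Bio import SeqIO, Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils import molecular_weight as _bio_mw

__all__ = [
    "MeltingCurve",
    "TmResult",
    "CalibrationCurve",
    "SequenceRecord",
    "tm_from_derivative",
    "tm_sigmoid_fit",
    "sec_calibrate",
    "predict_mw",
    "sequence_mw",
    "extinction_280",
    "identity_similarity",
    "read_fasta",
    "read_melting_curve",
    "read_sec_standards",
    "load_reference_sequences",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class MeltingCurve:
    """A thermal-unfolding fluorescence trace (temperatures in deg C)."""

    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, float)
        self.fluorescence = np.asarray(self.fluorescence, float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence arrays differ in length")
        if len(self.temperatures) < 10:
            raise ValueError("need at least 10 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not (np.all(np.isfinite(self.temperatures)) and np.all(np.isfinite(self.fluorescence))):
            raise ValueError("non-finite values in melting curve")


@dataclass
class TmResult:
    """Melting temperature and estimator diagnostics."""

    tm: float  # deg C
    method: str  # "derivative" or "sigmoid-fit"
    slope: float | None = None  # transition width (sigmoid s), deg C
    residual_norm: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.tm):
            raise ValueError("non-finite Tm")


@dataclass
class CalibrationCurve:
    """log10(MW[Da]) = slope * Ve[mL] + intercept."""

    slope: float
    intercept: float
    r_squared: float
    ve_min: float
    ve_max: float


@dataclass(frozen=True)
class SequenceRecord:
    """A one-letter protein sequence with an identifier."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        bad = sorted(set(self.sequence) - _AA)
        if bad:
            raise ValueError(f"{self.identifier}: invalid residue letters {bad}")


# ---------------------------------------------------------------------------
# melting curves
# ---------------------------------------------------------------------------

def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    if window == 1:
        return y
    pad = window // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def tm_from_derivative(curve: MeltingCurve, smoothing_window: int = 5) -> TmResult:
    """Tm as the temperature of the maximum smoothed dF/dT.

    Both the trace and its finite-difference derivative are smoothed with
    the same centered moving average.  Only the rising transition counts:
    the derivative maximum must exceed three times the median absolute
    derivative (noise floor), otherwise a flat or decreasing trace is
    reported as "no transition detected".  The peak is refined by a local
    quadratic fit over its five grid neighbours.
    """
    T = curve.temperatures
    F = _smooth(curve.fluorescence, smoothing_window)
    dF = _smooth(np.gradient(F, T), smoothing_window)
    noise_floor = 3.0 * np.median(np.abs(dF))
    i = int(np.argmax(dF))
    if dF[i] <= 0 or dF[i] <= noise_floor:
        raise ValueError("no transition detected (no rising slope above the noise floor)")
    tm = float(T[i])
    if 1 < i < len(T) - 2:
        idx = np.arange(i - 2, i + 3)
        a, b, _c = np.polyfit(T[idx] - T[i], dF[idx], 2)
        if a < 0:
            tm = float(T[i] + np.clip(-b / (2.0 * a), -(T[i] - T[i - 2]), T[i + 2] - T[i]))
    elif 0 < i < len(T) - 1:
        denom = dF[i - 1] - 2.0 * dF[i] + dF[i + 1]
        if abs(denom) > 1e-12:
            shift = float(np.clip(0.5 * (dF[i - 1] - dF[i + 1]) / denom, -1.0, 1.0))
            tm = float(T[i] + shift * (T[i + 1] - T[i - 1]) / 2.0)
    return TmResult(tm=tm, method="derivative", slope=None, residual_norm=None)


def _boltzmann(T, f_min, f_max, tm, s):
    return f_min + (f_max - f_min) / (1.0 + np.exp((tm - T) / s))


def tm_sigmoid_fit(curve: MeltingCurve) -> TmResult:
    """Least-squares Boltzmann fit over the pre-aggregation region.

    The fit window ends at the fluorescence maximum (post-peak aggregation
    decay is excluded); initial Tm comes from the derivative estimator.
    """
    imax = int(np.argmax(curve.fluorescence))
    T = curve.temperatures[: imax + 1]
    F = curve.fluorescence[: imax + 1]
    if len(T) < 5:
        raise ValueError("fewer than 5 points before the fluorescence maximum")
    try:
        t0 = tm_from_derivative(MeltingCurve(curve.temperatures, curve.fluorescence)).tm
    except ValueError:
        t0 = float(T[len(T) // 2])
    p0 = [float(F.min()), float(F.max()), t0, 2.0]
    try:
        popt, _ = curve_fit(_boltzmann, T, F, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise ValueError(f"sigmoid fit did not converge (start Tm {t0:.2f}): {exc}") from exc
    resid = F - _boltzmann(T, *popt)
    tm = float(popt[2])
    if not (curve.temperatures[0] <= tm <= curve.temperatures[-1]):
        raise ValueError(f"fitted Tm {tm:.2f} outside the measured range")
    return TmResult(
        tm=tm, method="sigmoid-fit", slope=float(abs(popt[3])), residual_norm=float(np.linalg.norm(resid))
    )


# ---------------------------------------------------------------------------
# SEC calibration
# ---------------------------------------------------------------------------

def sec_calibrate(standards: list[tuple[float, float]] | pd.DataFrame) -> CalibrationCurve:
    """Fit log10(MW) = a*Ve + b over (MW in Da, Ve in mL) standards."""
    if isinstance(standards, pd.DataFrame):
        pairs = list(zip(standards["mw"], standards["ve"]))
    else:
        pairs = list(standards)
    if len(pairs) < 2:
        raise ValueError("need at least two standards")
    mw = np.array([p[0] for p in pairs], float)
    ve = np.array([p[1] for p in pairs], float)
    if len(np.unique(ve)) != len(ve):
        raise ValueError("duplicate elution volumes in standards")
    if len(pairs) == 2:
        a = (np.log10(mw[1]) - np.log10(mw[0])) / (ve[1] - ve[0])
        b = np.log10(mw[0]) - a * ve[0]
        r2 = 1.0
    else:
        fit = linregress(ve, np.log10(mw))
        a, b, r2 = fit.slope, fit.intercept, fit.rvalue**2
    if a >= 0:
        warnings.warn("non-SEC-like calibration: slope is not negative", stacklevel=2)
    return CalibrationCurve(
        slope=float(a), intercept=float(b), r_squared=float(r2),
        ve_min=float(ve.min()), ve_max=float(ve.max()),
    )


def predict_mw(curve: CalibrationCurve, ve: float) -> tuple[float, bool]:
    """Apparent MW at an elution volume; flags extrapolation beyond the standards."""
    mw = 10.0 ** (curve.slope * ve + curve.intercept)
    extrapolated = not (curve.ve_min <= ve <= curve.ve_max)
    return float(mw), extrapolated


# ---------------------------------------------------------------------------
# sequence properties
# ---------------------------------------------------------------------------

def sequence_mw(seq: SequenceRecord | str) -> float:
    """Average-mass molecular weight in Da (residue masses plus one water)."""
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if not s:
        raise ValueError("empty sequence")
    SequenceRecord("query", s)
    return float(_bio_mw(s, seq_type="protein"))


def extinction_280(seq: SequenceRecord | str, assume_cystines: bool = False) -> float:
    """Molar extinction coefficient at 280 nm (M^-1 cm^-1).

    eps = 5500 * nTrp + 1490 * nTyr (+ 125 per cystine pair when
    ``assume_cystines``, pairing floor(nCys / 2) cysteines).
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    SequenceRecord("query", s)
    eps = 5500.0 * s.count("W") + 1490.0 * s.count("Y")
    if assume_cystines:
        eps += 125.0 * (s.count("C") // 2)
    return eps


def identity_similarity(
    seq_a: SequenceRecord | str,
    seq_b: SequenceRecord | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[float, float]:
    """Percent identity and similarity from a global affine-gap alignment.

    Identity counts identical aligned columns over columns where both
    sequences have a residue (gap columns excluded from the denominator);
    similarity additionally counts substitutions with a positive matrix
    score.  Both are reported to integer percent.  The computation is
    symmetric in its arguments.
    """
    a = seq_a.sequence if isinstance(seq_a, SequenceRecord) else seq_a
    b = seq_b.sequence if isinstance(seq_b, SequenceRecord) else seq_b
    if not a or not b:
        raise ValueError("empty sequence")
    SequenceRecord("a", a), SequenceRecord("b", b)
    if b < a:  # canonical order makes the result order-independent
        a, b = b, a
    sub = substitution_matrices.load(matrix)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    alignment = aligner.align(a, b)[0]
    cols = zip(alignment[0], alignment[1])
    n_both = n_ident = n_sim = 0
    for x, y in cols:
        if x == "-" or y == "-":
            continue
        n_both += 1
        if x == y:
            n_ident += 1
            n_sim += 1
        elif sub[x, y] > 0:
            n_sim += 1
    if n_both == 0:
        raise ValueError("alignment has no aligned residue pairs")
    return (round(100.0 * n_ident / n_both), round(100.0 * n_sim / n_both))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [
        SequenceRecord(identifier=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_melting_curve(path: str | Path) -> MeltingCurve:
    """TSV/CSV with temperature and fluorescence columns (T, F)."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    t = cols.get("t") or cols.get("temperature")
    f = cols.get("f") or cols.get("fluorescence")
    if t is None or f is None:
        raise ValueError("expected columns T/temperature and F/fluorescence")
    return MeltingCurve(df[t].to_numpy(), df[f].to_numpy())


def read_sec_standards(path: str | Path) -> pd.DataFrame:
    """TSV/CSV with mw (Da) and ve (mL) columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.lower() for c in df.columns]
    if "mw" not in df.columns or "ve" not in df.columns:
        raise ValueError("expected columns mw and ve")
    return df[["mw", "ve"]]


def load_reference_sequences() -> dict[str, SequenceRecord]:
    """Bundled Hsp90 C-terminal-domain reference sequences.

    Keys: ``human`` (full-length Hsp90-alpha), ``human_ctd`` (residues
    561-697), ``yeast_ctd`` (Hsp82 540-677) and ``ecoli_ctd`` (HtpG
    510-624).
    """
    with resources.as_file(resources.files("gbscan.data") / "sequences.fasta") as p:
        records = {r.identifier.split("|")[0]: r for r in read_fasta(p)}
    human = records["human"].sequence
    out = dict(records)
    out["human_ctd"] = SequenceRecord("human_ctd", human[560:697])
    return out
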