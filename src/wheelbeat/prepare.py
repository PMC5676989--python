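"""From a denoised frame to one clean ensemble heartbeat.

Pipeline: morphological R-peak detection -> fixed-window segmentation
(0.25 s before the R-peak, 0.40 s after) -> z-score amplitude normalisation
-> NCCC outlier rejection -> ensemble averaging.

NCCC (normalised cross-correlation clustering) is the stage this package
exists for.  It assumes that clean heartbeats of one subject recorded
seconds apart are highly similar, while false or noise-dominated "beats"
resemble nothing, including each other.  Each template is ranked by its
average maximum-lag normalised cross-correlation against the whole set
(self term included); a cluster is seeded with the top ``n`` templates and
grown greedily — the next-ranked template is admitted while
``m - A_i <= eps0 * m**2`` and ``A_i >= 0.5``, where ``m`` is the running
mean of the cluster members' ranks — stopping at the first rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sps

__all__ = [
    "HeartbeatTemplate",
    "TemplateSet",
    "NcccState",
    "EnsembleHeartbeat",
    "RpeakConfig",
    "detect_rpeaks",
    "segment",
    "zscore",
    "normalize_set",
    "max_ncc",
    "nccc_select",
    "build_ensemble",
    "prepare_frame",
]


@dataclass
class HeartbeatTemplate:
    """One fixed-length heartbeat segment and its R-peak position."""

    samples: np.ndarray
    rpeak: int
    normalised: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.normalised:
            if abs(self.samples.mean()) > 1e-9 or abs(self.samples.std() - 1) > 1e-9:
                raise ValueError("normalised template must have mean 0, SD 1")


@dataclass
class TemplateSet:
    """Ordered heartbeat templates extracted from one frame."""

    templates: list[HeartbeatTemplate]

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValueError("a template set needs at least one member")
        lengths = {t.samples.size for t in self.templates}
        if len(lengths) != 1:
            raise ValueError("all templates must have the same length")

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def __getitem__(self, i: int) -> HeartbeatTemplate:
        return self.templates[i]

    def as_matrix(self) -> np.ndarray:
        return np.stack([t.samples for t in self.templates])


@dataclass
class NcccState:
    """Full bookkeeping of one NCCC run (for reports and inspection)."""

    ncc: np.ndarray            # pairwise max-lag NCC matrix, unit diagonal
    averages: np.ndarray       # A_i per template
    order: np.ndarray          # template indices, descending A
    cluster: list[int]         # admitted template indices, admission order
    m: float                   # mean of cluster members' A at termination
    eps: float                 # eps0 * m**2 at termination
    n: int
    eps0: float


@dataclass
class EnsembleHeartbeat:
    """Pointwise average of the NCCC-selected templates of one frame."""

    samples: np.ndarray
    count: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.count < 1:
            raise ValueError("an ensemble needs at least one template")


# ----------------------------------------------------------------- R-peaks

@dataclass(frozen=True)
class RpeakConfig:
    """Morphological detector parameters.

    The filtering structuring element (0.02 s) is much shorter than the R
    deflection, so opening/closing erase impulsive spikes while the QRS
    survives; the peak-valley-extraction element (0.07 s) is wider than the
    R deflection, so the morphologically smoothed copy *loses* the R and the
    subtraction extracts it.  ``pve_open_first`` selects between the two
    readings of the extraction stage (filtered minus open-then-close, the
    default, or minus close-then-open).
    """

    filter_se_s: float = 0.02
    pve_se_s: float = 0.07
    pve_open_first: bool = True
    refractory_s: float = 0.25
    threshold_frac: float = 0.5


def _flat_se(width_s: float, fs: float) -> int:
    return max(int(round(width_s * fs)), 2)


def detect_rpeaks(signal: np.ndarray, fs: float,
                  cfg: RpeakConfig | None = None) -> np.ndarray:
    """Morphological (opening/closing) R-peak detector.

    Stage 1 averages the open-close and close-open filtered signals, which
    suppresses impulsive noise of both polarities.  Stage 2 (peak-valley
    extraction) subtracts a morphologically smoothed copy from the filtered
    signal, leaving sharp deflections as candidates.  R-peaks are the
    candidates exceeding an adaptive threshold (half the median of the five
    largest candidate values), at least one refractory period apart.
    """
    cfg = cfg or RpeakConfig()
    x = np.asarray(signal, dtype=float)
    if x.size < fs:
        raise ValueError("need at least 1 s of signal")
    if not np.any(x != x[0]):
        return np.array([], dtype=int)

    se1 = _flat_se(cfg.filter_se_s, fs)
    oc = ndimage.grey_closing(ndimage.grey_opening(x, size=se1), size=se1)
    co = ndimage.grey_opening(ndimage.grey_closing(x, size=se1), size=se1)
    filtered = 0.5 * (oc + co)

    se2 = _flat_se(cfg.pve_se_s, fs)
    if cfg.pve_open_first:
        smooth = ndimage.grey_closing(ndimage.grey_opening(filtered, size=se2),
                                      size=se2)
    else:
        smooth = ndimage.grey_opening(ndimage.grey_closing(filtered, size=se2),
                                      size=se2)
    pve = filtered - smooth

    top = np.sort(pve)[-5:]
    theta = cfg.threshold_frac * float(np.median(top))
    if theta <= 0:
        return np.array([], dtype=int)
    distance = max(int(round(cfg.refractory_s * fs)), 1)
    peaks, _ = sps.find_peaks(pve, height=theta, distance=distance)
    return peaks.astype(int)


# ------------------------------------------------------------ segmentation

PRE_S = 0.25
POST_S = 0.40


def template_length(fs: float) -> int:
    """Samples per heartbeat template: round(0.65 * fs)."""
    return int(round((PRE_S + POST_S) * fs))


def segment(signal: np.ndarray, rpeaks, fs: float) -> TemplateSet | None:
    """Fixed-window heartbeat cropping: 0.25 s before each R-peak, 0.40 s after.

    R-peaks whose window would cross the frame boundary are skipped.
    Returns ``None`` when no complete window fits (rather than an invalid
    empty set).  Templates are raw (not yet amplitude-normalised).
    """
    x = np.asarray(signal, dtype=float)
    pre = int(round(PRE_S * fs))
    length = template_length(fs)
    out = []
    for r in np.asarray(rpeaks, dtype=int):
        i0 = r - pre
        if i0 < 0 or i0 + length > x.size:
            continue
        out.append(HeartbeatTemplate(samples=x[i0:i0 + length], rpeak=int(r)))
    return TemplateSet(out) if out else None


def zscore(segment: np.ndarray) -> np.ndarray:
    """Amplitude normalisation: ``(x - mean(x)) / std(x)``, population SD.

    A zero-variance segment (a saturation plateau) is rejected with a
    ``ValueError``.
    """
    x = np.asarray(segment, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance segment (saturation plateau?)")
    return (x - x.mean()) / sd


def normalize_set(tset: TemplateSet) -> TemplateSet | None:
    """z-score every template, silently dropping zero-variance members."""
    kept = []
    for t in tset:
        try:
            kept.append(HeartbeatTemplate(zscore(t.samples), t.rpeak,
                                          normalised=True))
        except ValueError:
            continue
    return TemplateSet(kept) if kept else None


# ------------------------------------------------------------------- NCCC

def max_ncc(a: np.ndarray, b: np.ndarray, min_overlap_frac: float = 0.5
            ) -> float:
    """Maximum over integer lags of the zero-normalised cross-correlation.

    At each lag the correlation is computed on the overlapping support only
    (means and SDs of the overlapping parts), and lags with less than
    ``min_overlap_frac`` of the template overlapping are excluded — short
    overlaps produce spurious near-1 maxima.  Symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("templates must have equal length")
    L = a.size
    min_n = max(int(np.ceil(min_overlap_frac * L)), 2)

    # raw lagged inner products for every shift s in [-(L-1), L-1]
    raw = sps.correlate(a, b, mode="full", method="auto")
    s = np.arange(-(L - 1), L)
    n = L - np.abs(s)

    csa = np.concatenate([[0.0], np.cumsum(a)])
    csa2 = np.concatenate([[0.0], np.cumsum(a * a)])
    csb = np.concatenate([[0.0], np.cumsum(b)])
    csb2 = np.concatenate([[0.0], np.cumsum(b * b)])

    # overlapping support: a[max(0,s) : L+min(0,s)], b[max(0,-s) : L+min(0,-s)]
    # correlate(a,b)[s] = sum_j a[j] * b[j - s]
    a_lo = np.maximum(0, s)
    a_hi = L + np.minimum(0, s)
    b_lo = np.maximum(0, -s)
    b_hi = L + np.minimum(0, -s)
    sum_a = csa[a_hi] - csa[a_lo]
    sum_a2 = csa2[a_hi] - csa2[a_lo]
    sum_b = csb[b_hi] - csb[b_lo]
    sum_b2 = csb2[b_hi] - csb2[b_lo]

    num = raw - sum_a * sum_b / n
    var_a = sum_a2 - sum_a**2 / n
    var_b = sum_b2 - sum_b**2 / n
    denom = np.sqrt(np.maximum(var_a, 0.0) * np.maximum(var_b, 0.0))
    valid = (n >= min_n) & (denom > 0)
    if not np.any(valid):
        return 0.0
    r = num[valid] / denom[valid]
    return float(np.clip(r.max(), -1.0, 1.0))


def _ncc_matrix(tset: TemplateSet) -> np.ndarray:
    N = len(tset)
    ncc = np.eye(N)
    for i in range(N):
        for j in range(i + 1, N):
            ncc[i, j] = ncc[j, i] = max_ncc(tset[i].samples, tset[j].samples)
    return ncc


def nccc_select(tset: TemplateSet, n: int = 3, eps0: float = 0.1
                ) -> tuple[list[int], NcccState]:
    """Normalised cross-correlation clustering.

    1. NCC_ij = max-lag normalised cross-correlation between templates i, j
       (self term NCC_ii = 1 included);
    2. A_i = mean_j NCC_ij;
    3. order templates by descending A and seed the cluster with the first n;
    4. m = mean of cluster members' A;  eps = eps0 * m**2;
    5. admit the next template iff m - A_i <= eps and A_i >= 0.5;
    6. repeat 4-5, stopping at the first rejection.

    Returns the selected template indices (a prefix of the descending-A
    order) and the full :class:`NcccState`.  Sets of at most n templates are
    selected wholesale.
    """
    if n < 1:
        raise ValueError("initial cluster size must be at least 1")
    N = len(tset)
    ncc = _ncc_matrix(tset)
    A = ncc.mean(axis=1)
    order = np.argsort(-A, kind="stable")  # ties broken by template index

    cluster = list(order[:min(n, N)])
    m = float(np.mean(A[cluster]))
    eps = eps0 * m * m
    for idx in order[min(n, N):]:
        m = float(np.mean(A[cluster]))
        eps = eps0 * m * m
        if (m - A[idx] <= eps) and (A[idx] >= 0.5):
            cluster.append(int(idx))
        else:
            break
    state = NcccState(ncc=ncc, averages=A, order=order, cluster=list(cluster),
                      m=m, eps=eps, n=n, eps0=eps0)
    return [int(i) for i in cluster], state


def build_ensemble(tset: TemplateSet, selected) -> EnsembleHeartbeat:
    """Pointwise mean of the selected templates."""
    selected = list(selected)
    if not selected:
        raise ValueError("cannot build an ensemble from no templates")
    mat = np.stack([tset[i].samples for i in selected])
    return EnsembleHeartbeat(samples=mat.mean(axis=0), count=len(selected))


def prepare_frame(samples: np.ndarray, fs: float, n: int = 3,
                  eps0: float = 0.1, rpeak_cfg: RpeakConfig | None = None,
                  ) -> tuple[EnsembleHeartbeat | None, dict]:
    """Run the full preparation chain on one (already denoised) frame.

    Returns the ensemble heartbeat (or ``None`` when the frame yields no
    usable beat) and a report dict with detected peaks, per-template A
    values and the selected/rejected split.
    """
    report: dict = {"rpeaks": [], "selected": [], "rejected": [], "A": []}
    rpeaks = detect_rpeaks(samples, fs, rpeak_cfg)
    report["rpeaks"] = rpeaks.tolist()
    if rpeaks.size == 0:
        return None, report
    raw = segment(samples, rpeaks, fs)
    if raw is None:
        return None, report
    tset = normalize_set(raw)
    if tset is None:
        return None, report
    selected, state = nccc_select(tset, n=n, eps0=eps0)
    report["A"] = state.averages.tolist()
    report["selected"] = selected
    report["rejected"] = [int(i) for i in state.order if int(i) not in selected]
    return build_ensemble(tset, selected), report
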