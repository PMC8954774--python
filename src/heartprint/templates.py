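"""Scalogram templates, subject feature matrices and FastICA reduction.

A scalogram is the magnitude of the continuous wavelet transform of one
cardiac cycle, computed with a generalized Morse wavelet (gamma = 3,
time-bandwidth product P^2 = 60, hence beta = P^2/gamma = 20).  The analytic
wavelet is defined directly in the frequency domain,

    Psi(w) ∝ w^beta * exp(-w^gamma)   for w > 0,

unit-peak normalized, and the CWT is evaluated per scale by frequency-domain
multiplication.  Scalograms are rendered through a fixed blue->red colormap
and resized to square RGB images (56 or 224 px).  Per-subject templates are
flattened and concatenated into a subjects-by-features matrix, optionally
reduced with FastICA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .preprocess import CYCLE_LEN, CardiacCycle, CycleTemplateSet
from .synthetic import ConfigurationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MorseParams:
    """Generalized Morse wavelet family and the analyzed frequency grid.

    12 voices per octave over 1-40 Hz covers the band the filter passes.
    """

    gamma: float = 3.0
    p2: float = 60.0
    voices_per_octave: int = 12
    f_min_hz: float = 1.0
    f_max_hz: float = 40.0

    @property
    def beta(self) -> float:
        return self.p2 / self.gamma

    @property
    def peak_omega(self) -> float:
        """Angular frequency of the wavelet's spectral peak: (beta/gamma)^(1/gamma)."""
        return (self.beta / self.gamma) ** (1.0 / self.gamma)

    def validate(self) -> None:
        if self.gamma <= 0 or self.p2 <= 0:
            raise ConfigurationError("gamma and P^2 must be positive")
        if not (0 < self.f_min_hz < self.f_max_hz):
            raise ConfigurationError("frequency range must satisfy 0 < f_min < f_max")

    def frequencies(self) -> np.ndarray:
        """Analyzed center frequencies in Hz, high-frequency first."""
        self.validate()
        n_oct = np.log2(self.f_max_hz / self.f_min_hz)
        n = int(np.floor(n_oct * self.voices_per_octave)) + 1
        return self.f_max_hz * 2.0 ** (-np.arange(n) / self.voices_per_octave)


# 5-anchor blue -> cyan -> green -> yellow -> red colormap (cold to hot)
_CMAP_POS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
_CMAP_RGB = np.array([
    [0.0, 0.0, 1.0],
    [0.0, 1.0, 1.0],
    [0.0, 1.0, 0.0],
    [1.0, 1.0, 0.0],
    [1.0, 0.0, 0.0],
])


@dataclass
class ScalogramTemplate:
    """Square RGB rendering of one cycle's CWT magnitude."""

    image: np.ndarray
    size: int
    source_cycle: str = ""

    def __post_init__(self) -> None:
        if self.image.shape != (self.size, self.size, 3):
            raise ConfigurationError("scalogram image must be size x size x 3")


def compute_scalogram(cycle: CardiacCycle, fs: float,
                      params: MorseParams = MorseParams()) -> np.ndarray:
    """|CWT| of one cycle on the Morse scale grid (rows: high freq first).

    The cycle is reflection-padded before the FFT so the long low-frequency
    wavelets do not wrap around the 600-sample window.
    """
    params.validate()
    x = cycle.samples
    pad = x.size
    xp = np.concatenate([x[pad - 1 :: -1], x, x[: -pad - 1 : -1]])
    n = xp.size
    xf = np.fft.fft(xp)
    omega = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0 / fs)

    freqs = params.frequencies()
    scales = params.peak_omega / (2.0 * np.pi * freqs)
    beta, gamma = params.beta, params.gamma
    wp = params.peak_omega
    log_peak = beta * np.log(wp) - wp**gamma

    out = np.empty((freqs.size, x.size))
    pos = omega > 0
    for i, s in enumerate(scales):
        w = np.zeros(n)
        so = s * omega[pos]
        # unit-peak analytic Morse filter evaluated at s*omega
        w[pos] = np.exp(beta * np.log(so) - so**gamma - log_peak)
        coeff = np.fft.ifft(xf * w)
        out[i] = np.abs(coeff[pad : pad + x.size])
    return out


def to_rgb_image(magnitude: np.ndarray, size: int) -> ScalogramTemplate:
    """Min-max normalize a magnitude matrix, map through the blue->red
    colormap, and bilinearly resize to ``size`` x ``size``.

    A constant magnitude (no dynamic range) maps everywhere to the colormap
    midpoint.
    """
    if size not in (56, 224):
        raise ConfigurationError("template size must be 56 or 224")
    m = np.asarray(magnitude, dtype=float)
    if m.size == 0:
        raise ConfigurationError("empty magnitude matrix")
    lo, hi = m.min(), m.max()
    norm = np.full_like(m, 0.5) if hi <= lo else (m - lo) / (hi - lo)
    rgb = np.stack(
        [np.interp(norm, _CMAP_POS, _CMAP_RGB[:, ch]) for ch in range(3)], axis=-1
    )
    img = _sk_resize(rgb, (size, size), order=1, mode="edge", anti_aliasing=True,
                     preserve_range=True)
    return ScalogramTemplate(np.clip(img, 0.0, 1.0), size)


def scalogram_templates(tset: CycleTemplateSet, fs: float, size: int,
                        params: MorseParams = MorseParams()) -> list[ScalogramTemplate]:
    """One RGB scalogram per cycle of a template set, in temporal order."""
    out = []
    for i, cyc in enumerate(tset.cycles):
        tpl = to_rgb_image(compute_scalogram(cyc, fs, params), size)
        tpl.source_cycle = f"{tset.subject_id}/s{tset.session_id}/c{i}"
        out.append(tpl)
    return out


@dataclass
class SubjectFeatureMatrix:
    """Subjects-by-features matrix of concatenated templates.

    Flattening convention: template-major in temporal order; within an image,
    row-major with channel last.  ``unflatten`` inverts it exactly.
    """

    values: np.ndarray
    subject_ids: list[str]
    kind: str = "cycles"          # "cycles" | "scalograms"
    k: int = 0
    size: int = 0                 # image size for scalograms, 0 for cycles
    normalized: bool = False
    reduced: bool = False

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.subject_ids):
            raise ConfigurationError("row count must equal number of subjects")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def unflatten(self, row: int) -> np.ndarray:
        """Recover the stacked templates of one subject from their row."""
        if self.reduced:
            raise ConfigurationError("cannot unflatten a reduced matrix")
        if self.kind == "cycles":
            return self.values[row].reshape(self.k, CYCLE_LEN)
        return self.values[row].reshape(self.k, self.size, self.size, 3)


def concatenate_subject_templates(
    templates: dict[str, list], subject_ids: list[str] | None = None
) -> SubjectFeatureMatrix:
    """Stack each subject's templates (cycles or scalogram images) into one
    feature row.  All subjects must hold the same number of same-shape
    templates."""
    if subject_ids is None:
        subject_ids = sorted(templates)
    counts = {sid: len(templates[sid]) for sid in subject_ids}
    if len(set(counts.values())) != 1:
        bad = sorted({sid for sid in subject_ids if counts[sid] != max(counts.values())})
        raise ConfigurationError(f"ragged template counts for subjects: {bad}")

    def flat(tpl) -> np.ndarray:
        arr = tpl.samples if isinstance(tpl, CardiacCycle) else tpl.image
        return np.asarray(arr, dtype=float).ravel()

    rows = [np.concatenate([flat(t) for t in templates[sid]]) for sid in subject_ids]
    first = templates[subject_ids[0]][0]
    if isinstance(first, CardiacCycle):
        kind, size = "cycles", 0
    else:
        kind, size = "scalograms", first.size
    return SubjectFeatureMatrix(np.stack(rows), list(subject_ids), kind=kind,
                                k=counts[subject_ids[0]], size=size)


@dataclass
class ICAModel:
    """Fitted FastICA reduction of subject feature rows.

    Each training row is modelled as a mixture of ``n_components``
    independent source *waveforms* (each of feature length), exactly the
    orientation FastICA uses when handed a subjects-by-features matrix: the
    rows are the mixed signals and the features are the observation samples.
    A subject's reduced representation is their coefficient vector on the
    learned sources; a new (test) row is reduced by least-squares projection
    onto the same sources after removing its own mean.  Because the sources
    are whitened this projection is orthogonal, so distance geometry inside
    the training row space is preserved up to rotation and a global scale.
    """

    n_components: int
    sources: np.ndarray           # n_components x n_features
    projection: np.ndarray        # n_features x n_components
    mixing: np.ndarray            # n_train_rows x n_components
    seed: int
    tol: float
    effective_rank: int

    def transform(self, matrix: SubjectFeatureMatrix) -> SubjectFeatureMatrix:
        return transform_with_ica(matrix, self)


def fit_ica(train: SubjectFeatureMatrix, n_components: int = 63,
            seed: int = 0, tol: float = 1e-4, max_iter: int = 500) -> ICAModel:
    """Learn a FastICA source basis on the training rows only.

    Deflation variant with the logcosh contrast.  Sources and projection are
    learned exclusively from the training matrix; test-session rows are later
    projected through the same transform (no leakage).
    """
    X = train.values
    n_rows = X.shape[0]
    if n_components > n_rows:
        raise ConfigurationError(
            f"n_components={n_components} exceeds the {n_rows} training rows; reduce it"
        )
    Xc = X - X.mean(axis=1, keepdims=True)  # each mixture is centered
    sv = np.linalg.svd(Xc, compute_uv=False)
    rank = int(np.sum(sv > sv[0] * 1e-9)) if sv.size else 0
    if n_components > rank:
        raise ConfigurationError(
            f"n_components={n_components} exceeds the effective rank {rank} of the "
            "centered training matrix; reduce n_components"
        )

    with warnings.catch_warnings():
        warnings.simplefilter("always", ConvergenceWarning)
        ica = FastICA(n_components=n_components, algorithm="deflation",
                      fun="logcosh", tol=tol, max_iter=max_iter,
                      whiten="unit-variance", random_state=seed)
        # rows are mixtures of source waveforms -> hand FastICA the transpose
        sources = ica.fit_transform(X.T).T      # n_components x n_features
        if ica.n_iter_ >= max_iter:
            log.warning("FastICA hit max_iter=%d before tol=%g", max_iter, tol)
    projection = np.linalg.pinv(sources)        # n_features x n_components
    return ICAModel(n_components=n_components, sources=sources,
                    projection=projection, mixing=ica.mixing_.copy(),
                    seed=seed, tol=tol, effective_rank=rank)


def transform_with_ica(matrix: SubjectFeatureMatrix, model: ICAModel) -> SubjectFeatureMatrix:
    """Reduce rows to their least-squares coefficients on the ICA sources."""
    if matrix.n_features != model.sources.shape[1]:
        raise ConfigurationError(
            f"matrix has {matrix.n_features} features but the ICA model expects "
            f"{model.sources.shape[1]}"
        )
    centered = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    reduced = centered @ model.projection
    return SubjectFeatureMatrix(reduced, list(matrix.subject_ids), kind=matrix.kind,
                                k=matrix.k, size=matrix.size,
                                normalized=matrix.normalized, reduced=True)
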