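"""Daubechies filter banks, transform matrices and density-window alternatives.

The discrete wavelet transform is represented as an orthogonal matrix ``L``
whose rows are stride-2 circular shifts of the low-pass taps ``h`` (top block)
and high-pass taps ``g`` (bottom block); multiple levels compose the one-level
matrices in a pyramid, densified in level order (approximation first, then
details coarse to fine).  Periodic (circular) boundary handling keeps ``L``
square and orthogonal, so perfect reconstruction and Parseval energy
conservation hold exactly.

Density windows are drop-in alternatives to the wavelet taps: a unimodal
probability-density shape aligned with the R wave replaces the filter in the
same two-band construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import special, stats

# ---------------------------------------------------------------------------
# filter banks and transform matrices


@dataclass
class WaveletFilterPair:
    """Orthonormal low-pass / high-pass pair for one Daubechies family member.

    Invariants: ``sum(h) = sqrt(2)``, ``||h|| = 1`` and the quadrature-mirror
    relation ``g_k = (-1)^k h_{len-1-k}``.
    """

    name: str
    h: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if abs(self.h.sum() - np.sqrt(2.0)) > 1e-10:
            raise ValueError("low-pass taps must sum to sqrt(2)")
        if abs(np.linalg.norm(self.h) - 1.0) > 1e-10:
            raise ValueError("low-pass taps must have unit norm")
        mirror = np.array([(-1) ** k * self.h[len(self.h) - 1 - k] for k in range(len(self.h))])
        if np.max(np.abs(self.g - mirror)) > 1e-10:
            raise ValueError("high-pass taps must be the quadrature mirror of h")


def daubechies_filters(i: int) -> WaveletFilterPair:
    """Standard orthonormal Daubechies-``i`` pair (db1 = Haar .. db10)."""
    if not 1 <= i <= 10:
        raise ValueError(f"Daubechies order must be 1..10, got {i}")
    h = np.asarray(pywt.Wavelet(f"db{i}").rec_lo, dtype=float)
    g = np.array([(-1) ** k * h[len(h) - 1 - k] for k in range(len(h))])
    return WaveletFilterPair(name=f"db{i}", h=h, g=g)


@dataclass
class TransformMatrixL:
    """Level-ordered orthogonal wavelet transform matrix (periodic boundary)."""

    matrix: np.ndarray
    levels: int
    filter: WaveletFilterPair
    boundary: str = "periodic"

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def level_slices(self) -> dict[str, slice]:
        """Row ranges of each band: ``A{J}`` then ``D{J}`` .. ``D1``."""
        d, J = self.d, self.levels
        out = {f"A{J}": slice(0, d >> J)}
        start = d >> J
        for j in range(J, 0, -1):
            size = d >> j
            out[f"D{j}"] = slice(start, start + size)
            start += size
        return out


def _one_level_matrix(fp: WaveletFilterPair, m: int) -> np.ndarray:
    if m % 2:
        raise ValueError("one-level analysis needs an even length")
    if m < len(fp.h):
        raise ValueError(f"length {m} shorter than filter {fp.name}")
    L = np.zeros((m, m))
    k = np.arange(len(fp.h))
    for i in range(m // 2):
        cols = (2 * i + k) % m
        L[i, cols] += fp.h
        L[m // 2 + i, cols] += fp.g
    return L


def max_levels(d: int, filter_len: int, cap: int = 3) -> int:
    """Largest decomposition depth J <= ``cap`` exactly supported at length d."""
    J = 0
    m = d
    while J < cap and m % 2 == 0 and m // 2 >= filter_len // 2 and m >= filter_len:
        J += 1
        m //= 2
    return max(J, 1)


def build_L_matrix(fp: WaveletFilterPair, d: int, J: int = 1) -> TransformMatrixL:
    """Compose the J-level pyramid transform matrix of size ``d`` x ``d``.

    Requires ``d`` divisible by ``2^J`` with at least a filter's worth of
    approximation coefficients remaining at the coarsest level.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    if d < len(fp.h):
        raise ValueError(f"d={d} shorter than the {fp.name} filter")
    if d % (1 << J):
        raise ValueError(f"d={d} not divisible by 2^{J}")
    if (d >> (J - 1)) < len(fp.h):
        raise ValueError(f"J={J} too deep: fewer than filter-length approximations remain")
    total = np.eye(d)
    for j in range(1, J + 1):
        m = d >> (j - 1)
        step = np.eye(d)
        step[:m, :m] = _one_level_matrix(fp, m)
        total = step @ total
    return TransformMatrixL(matrix=total, levels=J, filter=fp)


def dwt(signal: np.ndarray, fp: WaveletFilterPair, J: int) -> np.ndarray:
    """Multilevel periodic DWT, coefficients in level order ``[A_J, D_J..D_1]``.

    ``J = 0`` is an identity pass-through.  Matches the matrix transform to
    rounding error while being computed by iterated circular correlation and
    downsampling.
    """
    x = np.asarray(signal, dtype=float)
    if J == 0:
        return x.copy()
    if len(x) % (1 << J):
        raise ValueError(f"signal length {len(x)} not divisible by 2^{J}")
    details = []
    approx = x
    for _ in range(J):
        m = len(approx)
        if m < len(fp.h):
            raise ValueError("signal too short for this decomposition depth")
        idx = (2 * np.arange(m // 2)[:, None] + np.arange(len(fp.h))[None, :]) % m
        details.append(approx[idx] @ fp.g)
        approx = approx[idx] @ fp.h
    return np.concatenate([approx] + details[::-1])


def idwt(coeffs: np.ndarray, fp: WaveletFilterPair, J: int) -> np.ndarray:
    """Inverse of :func:`dwt` (orthogonal perfect reconstruction)."""
    c = np.asarray(coeffs, dtype=float)
    if J == 0:
        return c.copy()
    d = len(c)
    approx = c[: d >> J].copy()
    start = d >> J
    for j in range(J, 0, -1):
        size = d >> j
        detail = c[start : start + size]
        start += size
        m = 2 * size
        x = np.zeros(m)
        for i in range(size):
            cols = (2 * i + np.arange(len(fp.h))) % m
            x[cols] += approx[i] * fp.h + detail[i] * fp.g
        approx = x
    return approx


def strang_convert(L: TransformMatrixL, beat: np.ndarray) -> np.ndarray:
    """Dense level-ordered coefficient block of ``L`` applied to one beat.

    This is the densified form of the sparse banded product: approximation
    coefficients first, then detail coefficients from coarse to fine.
    """
    beat = np.asarray(beat, dtype=float)
    if beat.shape != (L.d,):
        raise ValueError(f"beat length {beat.shape} does not match d={L.d}")
    return L.matrix @ beat


@dataclass
class CoefficientMatrixH:
    """Concatenated per-beat wavelet (or density) coefficient blocks.

    ``matrix`` stacks one coefficient row per beat; ``per_beat_blocks`` maps
    beat index to its half-open row range.
    """

    matrix: np.ndarray
    per_beat_blocks: dict[int, tuple[int, int]]
    levels: int
    filter_name: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("coefficient matrix contains non-finite values")

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


def assemble_H(beats: list[np.ndarray], fp: WaveletFilterPair, J: int = 1) -> CoefficientMatrixH:
    """Stack per-beat Strang coefficient blocks into the H matrix."""
    if not beats:
        raise ValueError("no beats given")
    arr = np.asarray([np.asarray(b, dtype=float) for b in beats])
    if arr.ndim != 2:
        raise ValueError("all beats must share the same window length d")
    L = build_L_matrix(fp, arr.shape[1], J)
    mat = arr @ L.matrix.T
    blocks = {i: (i, i + 1) for i in range(len(beats))}
    return CoefficientMatrixH(matrix=mat, per_beat_blocks=blocks, levels=J, filter_name=fp.name)


def wavelet_feature_basis(
    filter_name: str | WaveletFilterPair,
    d: int,
    J: int | None = None,
    keep: str = "approx",
) -> np.ndarray:
    """Wavelet coordinate system used as H in the modified ICA fit.

    Returns the level-ordered transform rows, optionally truncated:

    * ``keep="all"`` — the full orthogonal d x d transform (a pure rotation);
    * ``keep="approx"`` (default) — approximation rows plus all but the finest
      detail band.  Dropping the finest details is what makes H
      information-bearing: the fit then runs in a smooth wavelet subspace
      aligned with the beat morphology rather than in raw sample space.
    """
    fp = daubechies_filters(int(filter_name[2:])) if isinstance(filter_name, str) else filter_name
    if J is None:
        J = max_levels(d, len(fp.h))
    L = build_L_matrix(fp, d, J)
    if keep == "all":
        return L.matrix.copy()
    if keep == "approx":
        return L.matrix[: d - (d >> 1)].copy()  # drop the finest detail band D1
    raise ValueError(f"unknown keep mode {keep!r}")


# ---------------------------------------------------------------------------
# density-function alternatives


@dataclass
class DensityWindow:
    """A unimodal density shape on the beat window, mode-aligned with the R wave."""

    function_id: str
    params: dict = field(default_factory=dict)
    values: np.ndarray = None
    t_R: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")
        if np.any(self.values < 0):
            raise ValueError("density values must be nonnegative")


_DENSITY_IDS = ("F1", "F2", "F3", "F4", "F5", "F6")


def density_window(
    function_id: str,
    d: int,
    tR: int,
    params: dict | None = None,
    garbled: bool = False,
    seed: int | None = None,
) -> DensityWindow:
    """Evaluate one of the six density families on the window grid.

    F1 Poisson (continuous ``t``, factorial via the gamma function), F2
    double-exponential, F3 Student-t, F4 normal, F5 lognormal (grid starts at
    ``t = 1``), F6 log-logistic density.  For each family the parameters are
    fitted, unless given, so the mode aligns with ``tR``.  ``garbled`` exposes
    the verbatim printed variants of F3 (Gaussian kernel times a chi-square
    draw times ``r_d``) and F6 (the log-logistic CDF); these do not satisfy
    the mode-alignment invariant and exist for reproducibility only.
    """
    if function_id not in _DENSITY_IDS:
        raise ValueError(f"unknown density id {function_id!r}")
    if not 0 <= tR < d:
        raise ValueError("tR must lie inside the window")
    p = dict(params or {})
    t = np.arange(d, dtype=float)

    if function_id == "F1":
        lam = p.setdefault("lam", float(np.exp(special.digamma(tR + 1))))
        if lam <= 0:
            raise ValueError("lambda must be positive")
        vals = np.exp(t * np.log(lam) - special.gammaln(t + 1.0) - lam)
    elif function_id == "F2":
        lam = p.setdefault("lam", max(d / 10.0, 1.0))
        if lam <= 0:
            raise ValueError("lambda must be positive")
        vals = np.exp(-np.abs(t - tR) / lam) / lam
        p["t_R"] = tR
    elif function_id == "F3":
        rd = int(p.setdefault("r_d", d))
        sigma = p.setdefault("sigma", d / 12.0)
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        p.setdefault("mu", float(tR))
        if garbled:
            rng = np.random.default_rng(seed)
            z = float(rng.chisquare(1))
            vals = stats.norm.pdf(t, loc=p["mu"], scale=sigma) * z * rd
            p["z"] = z
        else:
            vals = stats.t.pdf(t, df=rd, loc=p["mu"], scale=sigma)
    elif function_id == "F4":
        sigma = p.setdefault("sigma", d / 12.0)
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        mu = p.setdefault("mu", float(tR))
        vals = stats.norm.pdf(t, loc=mu, scale=sigma)
    elif function_id == "F5":
        tg = t + 1.0  # first time index in the window cannot be zero
        sigma = p.setdefault("sigma", 0.35)
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        mu = p.setdefault("mu", float(np.log(tR + 1.0) + sigma**2))
        vals = np.exp(-((np.log(tg) - mu) ** 2) / (2 * sigma**2)) / (
            sigma * np.sqrt(2 * np.pi) * tg
        )
    else:  # F6
        tg = t + 1.0
        sigma = p.setdefault("sigma", 0.2)
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        beta = p.setdefault("beta", 1.0 / sigma)
        if garbled:
            alpha = p.setdefault("alpha", float(np.exp(p.get("mu", np.log(tR + 1.0)))))
            vals = 1.0 / (1.0 + (tg / alpha) ** (-beta))
        else:
            if beta <= 1:
                raise ValueError("log-logistic mode requires beta > 1")
            mode_factor = ((beta - 1.0) / (beta + 1.0)) ** (1.0 / beta)
            alpha = p.setdefault("alpha", (tR + 1.0) / mode_factor)
            u = (tg / alpha) ** beta
            vals = (beta / alpha) * (tg / alpha) ** (beta - 1.0) / (1.0 + u) ** 2

    win = DensityWindow(function_id=function_id, params=p, values=vals, t_R=tR)
    if not garbled and "lam" not in (params or {}):
        if abs(int(np.argmax(win.values)) - tR) > 1:
            raise AssertionError(f"{function_id}: mode not aligned with tR")
    return win


def density_basis(window: DensityWindow, d: int | None = None, keep: str = "approx") -> np.ndarray:
    """Two-band stride-2 matrix built from a density window, mirroring ``L``.

    The density values (rescaled to unit maximum — only the shape matters in
    the mixing-matrix role) replace the low-pass taps; their alternating-sign
    mirror replaces the high-pass taps.  ``keep="approx"`` returns only the
    low band, the default H for density-modified ICA.
    """
    w = np.asarray(window.values, dtype=float)
    if d is None:
        d = len(w)
    if len(w) != d:
        raise ValueError("density window length must equal d")
    if d % 2:
        raise ValueError("d must be even")
    peak = np.max(np.abs(w))
    if peak > 0:
        w = w / peak
    g = np.array([(-1) ** k * w[d - 1 - k] for k in range(d)])
    B = np.zeros((d, d))
    k = np.arange(d)
    for i in range(d // 2):
        cols = (2 * i + k) % d
        B[i, cols] += w
        B[d // 2 + i, cols] += g
    if keep == "approx":
        return B[: d // 2]
    if keep == "all":
        return B
    raise ValueError(f"unknown keep mode {keep!r}")


def assemble_H_from_density(beats: list[np.ndarray], window: DensityWindow) -> CoefficientMatrixH:
    """Per-beat coefficient blocks using a density window in place of the filter."""
    if not beats:
        raise ValueError("no beats given")
    arr = np.asarray([np.asarray(b, dtype=float) for b in beats])
    if arr.ndim != 2:
        raise ValueError("all beats must share the same window length d")
    d = arr.shape[1]
    if len(window.values) != d:
        raise ValueError("density window length must equal beat length")
    B = density_basis(window, d, keep="all")
    mat = arr @ B.T
    blocks = {i: (i, i + 1) for i in range(len(beats))}
    return CoefficientMatrixH(
        matrix=mat, per_beat_blocks=blocks, levels=1, filter_name=window.function_id
    )
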