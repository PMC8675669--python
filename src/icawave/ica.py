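"""Statistical core: entropy measures, Hotelling PCA and the modified ICA fit.

The mixing model is ``X = A S H + E``: rows of ``X`` are beat windows, ``H``
is a wavelet coordinate matrix, rows of ``S`` are independent components in
wavelet coordinates and rows of ``A`` are the per-beat mixing coefficients —
the extracted features.  Components are estimated per class by fixed-point
negentropy maximization with a log-cosh contrast (maximizing negentropy of
the outputs is equivalent to minimizing their mutual information).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from icawave.records import AAMI_CLASSES

# ---------------------------------------------------------------------------
# information measures


def entropy(p) -> float:
    """Shannon entropy in bits of a probability vector; ``0 log 0 := 0``."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def mutual_information(X: np.ndarray) -> float:
    """Histogram estimate of multi-channel mutual information in bits.

    ``I = sum_j H(X_j) - H(X_joint)`` with Freedman-Diaconis binning per
    channel and the joint histogram on the product grid.  Nonnegative up to
    estimator noise.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a (samples x channels) array with >= 2 channels")
    if X.shape[0] < 100:
        raise ValueError("need at least 100 samples")
    edges = []
    for j in range(X.shape[1]):
        e = np.histogram_bin_edges(X[:, j], bins="fd")
        if len(e) < 3:
            e = np.histogram_bin_edges(X[:, j], bins=10)
        edges.append(e)
    marg = 0.0
    for j in range(X.shape[1]):
        counts, _ = np.histogram(X[:, j], bins=edges[j])
        marg += entropy(counts / counts.sum())
    joint_counts, _ = np.histogramdd(X, bins=edges)
    joint = entropy(joint_counts.ravel() / joint_counts.sum())
    return marg - joint


def _log_cosh(z: np.ndarray) -> np.ndarray:
    """Overflow-safe ``log cosh z = |z| + log1p(exp(-2|z|)) - log 2``."""
    az = np.abs(z)
    return az + np.log1p(np.exp(-2.0 * az)) - np.log(2.0)


@functools.lru_cache(maxsize=1)
def _logcosh_gauss_expectation() -> float:
    """``E[log cosh nu]`` for standard normal ``nu``, by quadrature."""
    val, _ = integrate.quad(
        lambda z: _log_cosh(np.asarray(z)) * stats.norm.pdf(z), -40.0, 40.0,
        epsabs=1e-13, epsrel=1e-13, limit=200,
    )
    return float(val)


def negentropy(x: np.ndarray) -> float:
    """Log-cosh negentropy approximation ``J = (E[G(x)] - E[G(nu)])^2``.

    The sample is standardized internally (the Gaussian reference shares the
    variance of ``x``), so ``J`` is invariant to affine rescaling; it is zero
    for Gaussian data and grows with non-Gaussianity.
    """
    x = np.asarray(x, dtype=float).ravel()
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("negentropy undefined for a constant sample")
    z = (x - x.mean()) / sd
    return float((np.mean(_log_cosh(z)) - _logcosh_gauss_expectation()) ** 2)


# ---------------------------------------------------------------------------
# Hotelling PCA


@dataclass
class PCAResult:
    """Principal components by repeated variance maximization and deflation."""

    B: np.ndarray  # (variables x components) coefficient matrix
    S: np.ndarray  # (observations x components) component scores
    explained_variance: np.ndarray  # fractions, non-increasing
    mean: np.ndarray


def _leading_eigvec(C: np.ndarray, tol: float = 1e-12, max_iter: int = 1000):
    """Power iteration for the leading eigenpair, deterministic start."""
    m = C.shape[0]
    v = np.ones(m) / np.sqrt(m)
    d = np.diag(C)
    j = int(np.argmax(d))
    v[j] += 1.0
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_iter):
        w = C @ v
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0, v
        w /= nw
        if np.dot(w, v) < 0:
            w = -w
        lam_new = float(w @ C @ w)
        if np.max(np.abs(w - v)) < tol and abs(lam_new - lam) <= tol * max(lam_new, 1.0):
            v, lam = w, lam_new
            break
        v, lam = w, lam_new
    return lam, v


def hotelling_pca(
    X: np.ndarray,
    var_target: float = 1.0,
    n_components: int | None = None,
    method: str = "auto",
) -> PCAResult:
    """PCA by Hotelling deflation: extract the maximal-variance component,
    subtract its contribution from the covariance, repeat.

    Components are extracted until the cumulative explained variance reaches
    ``var_target`` (or ``n_components`` is hit); a request beyond the rank is
    truncated with a warning.  ``method="deflation"`` runs the literal power
    iteration + deflation loop; ``"svd"`` computes the identical decomposition
    via singular values (used for wide matrices where forming the covariance
    is wasteful); ``"auto"`` picks by size.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 observations")
    if not 0 < var_target <= 1:
        raise ValueError("var_target must be in (0, 1]")
    n, m = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    if method == "auto":
        method = "deflation" if m <= 200 else "svd"

    if method == "svd":
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        lams = s**2 / (n - 1)
        vecs = Vt
    elif method == "deflation":
        C = Xc.T @ Xc / (n - 1)
        lams_list, vecs_list = [], []
        for _ in range(min(n, m)):
            lam, v = _leading_eigvec(C)
            if lam <= 1e-12 * max(np.trace(C) + sum(lams_list), 1e-300):
                break
            lams_list.append(lam)
            vecs_list.append(v)
            C = C - lam * np.outer(v, v)
        lams = np.array(lams_list)
        vecs = np.array(vecs_list) if vecs_list else np.zeros((0, m))
    else:
        raise ValueError(f"unknown method {method!r}")

    total = float(np.sum(Xc * Xc) / (n - 1))
    if total <= 0:
        raise ValueError("zero total variance")
    frac = lams / total
    cum = np.cumsum(frac)
    k = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    k = min(k, len(lams))
    if n_components is not None:
        if n_components > len(lams):
            import warnings

            warnings.warn(
                f"requested {n_components} components but rank is {len(lams)}; truncating"
            )
        k = min(n_components, len(lams))
    # sign convention: largest-magnitude loading positive
    Bv = vecs[:k].copy()
    for r in range(k):
        j = int(np.argmax(np.abs(Bv[r])))
        if Bv[r, j] < 0:
            Bv[r] = -Bv[r]
    B = Bv.T
    return PCAResult(B=B, S=Xc @ B, explained_variance=frac[:k], mean=mean)


# ---------------------------------------------------------------------------
# modified ICA fit


@dataclass
class ClassComponentModel:
    """Per-class independent components with the stored feature projection.

    Rows of ``X_class`` are observations (beats); the fitted factorization is
    ``Y = A S`` in wavelet coordinates, with the columns of ``A`` maximally
    independent across beats and the rows of ``S`` the component patterns.
    ``projection`` maps a raw beat window (length ``d``) straight to its
    ``q`` mixing coefficients; the wavelet transform is folded in at fit time
    so no transform is computed per test beat.
    """

    class_label: str | None
    A: np.ndarray  # (n_class_beats x q) training mixing coefficients
    S: np.ndarray  # (q x r) component patterns in H coordinates
    projection: np.ndarray  # (d x q) raw-beat -> coefficients map
    unmixing: np.ndarray  # (q x q) orthonormal rotation in whitened space
    unmixing_total: np.ndarray  # (q x r) H-coordinates -> coefficients map
    whitening: dict
    q: int
    converged: bool
    iterations: int
    negentropy_per_component: np.ndarray
    basis: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.projection is not None


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(W @ W.T)
    vals = np.clip(vals, 1e-12, None)
    return vecs @ np.diag(vals**-0.5) @ vecs.T @ W


def _fastica_symmetric(Z: np.ndarray, q: int, max_iter: int, tol: float,
                       rng: np.random.Generator):
    r = Z.shape[1]
    W = _sym_decorrelate(rng.standard_normal((q, q)))
    for it in range(1, max_iter + 1):
        WZ = W @ Z
        g = np.tanh(WZ)
        g_prime = np.mean(1.0 - g * g, axis=1)
        W_new = (g @ Z.T) / r - g_prime[:, None] * W
        W_new = _sym_decorrelate(W_new)
        # convergence: max absolute change of the unmixing rows (up to sign)
        delta = float(
            np.max(np.minimum(np.abs(W_new - W), np.abs(W_new + W)).max(axis=1))
        )
        W = W_new
        if delta < tol:
            return W, it, True
    return W, max_iter, False


def _fastica_deflation(Z: np.ndarray, q: int, max_iter: int, tol: float,
                       rng: np.random.Generator):
    r = Z.shape[1]
    W = np.zeros((q, Z.shape[0]))
    iters = 0
    ok = True
    for c in range(q):
        w = rng.standard_normal(Z.shape[0])
        w -= W[:c].T @ (W[:c] @ w)
        w /= np.linalg.norm(w)
        converged = False
        for it in range(1, max_iter + 1):
            wz = w @ Z
            g = np.tanh(wz)
            w_new = (Z @ g) / r - np.mean(1.0 - g * g) * w
            w_new -= W[:c].T @ (W[:c] @ w_new)
            w_new /= np.linalg.norm(w_new)
            delta = float(min(np.abs(w_new - w).max(), np.abs(w_new + w).max()))
            w = w_new
            if delta < tol:
                converged = True
                iters = max(iters, it)
                break
        if not converged:
            ok = False
            iters = max_iter
        W[c] = w
    return W, iters, ok


def fit_class_components(
    X_class: np.ndarray,
    H: np.ndarray | None,
    q: int,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int | None = None,
    class_label: str | None = None,
) -> ClassComponentModel:
    """Fit ``q`` independent components to one class's beats under basis ``H``.

    Steps: (1) express beats in the wavelet coordinate system,
    ``Y = X H^+`` (the exact transpose when ``H`` has orthonormal rows);
    (2) whiten to ``q`` dimensions across the beat axis; (3) symmetric
    fixed-point negentropy maximization with the log-cosh contrast and
    symmetric decorrelation each step, capped at ``max_iter`` iterations,
    with a deflation fallback on non-convergence; (4) the per-beat mixing
    coefficients ``A`` are the recovered independent scores, the component
    patterns ``S`` their least-squares counterpart (so ``Y ~ A S``), and
    ``H`` is folded into the stored projection: extracting features from a
    test beat costs one ``d x q`` product.
    """
    X = np.asarray(X_class, dtype=float)
    if X.ndim != 2:
        raise ValueError("X_class must be 2-D (beats x samples)")
    if X.shape[0] < 2:
        raise ValueError("need at least two beats")
    if not np.all(np.isfinite(X)):
        raise ValueError("X_class contains non-finite values")
    n, d = X.shape
    if H is None:
        B = np.eye(d)
        r = d
    else:
        H = np.asarray(H, dtype=float)
        if H.shape[1] != d:
            raise ValueError(f"H has {H.shape[1]} columns, beats have {d} samples")
        r = H.shape[0]
        gram = H @ H.T
        if np.allclose(gram, np.eye(r), atol=1e-8):
            B = H.T
        else:
            B = np.linalg.pinv(H)
    if q > min(n, r):
        raise ValueError(f"q={q} exceeds the attainable rank min({n}, {r})")

    Y = X @ B  # (n x r): beats expressed in H coordinates
    col_means = Y.mean(axis=0, keepdims=True)
    Yc = Y - col_means

    # whiten across beats: q maximal-variance directions of the r coordinates
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    if s[q - 1] <= 1e-10 * s[0]:
        raise ValueError(f"data rank below q={q}")
    # Z = Yc @ K.T has identity sample covariance
    K = np.sqrt(n) * (Vt[:q] / s[:q, None])  # (q x r)
    Z = np.sqrt(n) * U[:, :q]

    rng = np.random.default_rng(seed)
    W, iters, converged = _fastica_symmetric(Z.T, q, max_iter, tol, rng)
    if not converged:
        W, iters, converged = _fastica_deflation(Z.T, q, max_iter, tol, rng)

    unmix_total = W @ K  # (q x r): H-coordinates -> independent scores
    A = Z @ W.T  # (n x q) per-beat mixing coefficients = features
    S = np.linalg.pinv(A) @ Yc  # (q x r) component patterns, Yc ~ A S

    projection = B @ unmix_total.T  # (d x q), strictly linear in the beat

    neg = np.array([negentropy(A[:, i]) for i in range(q)])
    return ClassComponentModel(
        class_label=class_label,
        A=A,
        S=S,
        projection=projection,
        unmixing=W,
        unmixing_total=unmix_total,
        whitening={"map": K, "singular_values": s[:q], "col_means": col_means},
        q=q,
        converged=converged,
        iterations=iters,
        negentropy_per_component=neg,
        basis=B,
    )


@dataclass
class FeatureVector:
    """Concatenated per-class mixing coefficients for one beat."""

    values: np.ndarray
    layout: dict[str, tuple[int, int]] = field(default_factory=dict)


def extract_features(
    beat: np.ndarray,
    models: dict[str, ClassComponentModel] | list[ClassComponentModel],
    class_order: tuple[str, ...] = AAMI_CLASSES,
) -> FeatureVector:
    """Project one raw beat through every class model and concatenate.

    Fixed class order N, S, V, F; the result has ``sum_c q_c`` entries and is
    linear in the beat (a zero beat maps to a zero vector).
    """
    if isinstance(models, list):
        models = {m.class_label: m for m in models}
    beat = np.asarray(beat, dtype=float).ravel()
    parts = []
    layout = {}
    pos = 0
    for c in class_order:
        if c not in models:
            raise ValueError(f"no fitted model for class {c!r}")
        m = models[c]
        if not m.fitted:
            raise ValueError(f"model for class {c!r} is not fitted")
        if m.projection.shape[0] != len(beat):
            raise ValueError("beat length does not match the fitted window size")
        v = beat @ m.projection
        parts.append(v)
        layout[c] = (pos, pos + len(v))
        pos += len(v)
    return FeatureVector(values=np.concatenate(parts), layout=layout)


# ---------------------------------------------------------------------------
# recovery diagnostics


def amari_index(P: np.ndarray) -> float:
    """Amari permutation/scale-invariant distance of ``P = W_est @ A_true``.

    Zero when ``P`` is a scaled permutation (perfect recovery up to the ICA
    ambiguities); normalized to at most 1.
    """
    P = np.abs(np.asarray(P, dtype=float))
    q = P.shape[0]
    if P.shape != (q, q):
        raise ValueError("P must be square")
    row = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    col = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((row + col) / (2 * q * (q - 1)))


def match_sources(S_est: np.ndarray, S_true: np.ndarray) -> tuple[np.ndarray, float]:
    """Greedy |correlation| matching of estimated to true sources.

    Returns the per-pair absolute correlations and their mean.
    """
    q = S_est.shape[0]
    C = np.corrcoef(S_est, S_true)[:q, q:]
    C = np.abs(C)
    used_r, used_c, corrs = set(), set(), []
    flat = sorted(
        ((C[i, j], i, j) for i in range(q) for j in range(C.shape[1])), reverse=True
    )
    for val, i, j in flat:
        if i in used_r or j in used_c:
            continue
        used_r.add(i)
        used_c.add(j)
        corrs.append(val)
        if len(corrs) == min(q, C.shape[1]):
            break
    corrs = np.array(corrs)
    return corrs, float(corrs.mean())
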