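"""Supervised spectral filters for two-class iEEG discrimination.

Each filter is a unit weight vector ``u`` over the FFT bins of one frequency
band (optionally per channel), replacing the uniform band average (PBF) with
a weighted average that emphasises the bins that separate preictal from
interictal windows.  Five supervised objectives are provided, all quadratic
in ``u`` so that the optimum is the dominant eigenvector of a symmetric
matrix ``M`` built from class-conditional moments:

``DM``
    maximise ``E[u . (Z - Y)]`` — closed form, ``u`` is the normalised
    difference of class means (no eigenproblem).
``VAR``
    maximise ``Var(u . Z) - Var(u . Y)``; ``M = E[ZZ'] - E[YY'] -
    E[Z]E[Z]' + E[Y]E[Y]'``.
``TVM``
    maximise ``(E[u . (Z - Y)])^2 + Var(u . Z) - Var(u . Y)``;
    ``M = E[ZZ'] - E[YY'] + (E[Y] - E[Z])E[Y]' + E[Y](E[Y] - E[Z])'``.
``DS``
    maximise ``E[(u . Z)^2 - (u . Y)^2]``; ``M = E[ZZ'] - E[YY']``.
``SqD``
    maximise ``E[(u . (Z - Y))^2]``; ``M = E[(Z - Y)(Z - Y)']`` with ``Z``
    and ``Y`` drawn independently.

``Z`` denotes a feature vector from class 0 (interictal) and ``Y`` from
class 1 (preictal).  The feature dimension — FFT bins over a 60 s window —
runs to the hundreds of thousands, so ``M`` is never materialised: every
objective is expressed as a matrix-free matvec over the stored class sample
matrices, and the dominant eigenpair is found by power iteration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .spectral import CANONICAL_BANDS, BandDefinition, SpectralTensor, band_bin_ranges

SUPERVISED_METHODS = ("DM", "VAR", "TVM", "DS", "SqD")
ALL_METHODS = ("PBF",) + SUPERVISED_METHODS
EIGEN_METHODS = ("VAR", "TVM", "DS", "SqD")


class DegenerateOperatorError(RuntimeError):
    """Power iteration started on an operator that maps the start vector to zero."""


@dataclass
class MomentSet:
    """Class-conditional first moments plus matrix-free second-moment products.

    Backed by the stored class sample matrices ``samples0`` (interictal,
    ``n0 x d``) and ``samples1`` (preictal, ``n1 x d``); the raw second-moment
    products ``E[ZZ'] v`` and ``E[YY'] v`` are computed as
    ``X'(Xv)/n`` without ever forming a ``d x d`` matrix.
    """

    samples0: np.ndarray
    samples1: np.ndarray

    def __post_init__(self) -> None:
        self.samples0 = np.atleast_2d(np.asarray(self.samples0, dtype=float))
        self.samples1 = np.atleast_2d(np.asarray(self.samples1, dtype=float))
        if self.samples0.shape[1] != self.samples1.shape[1]:
            raise ValueError(
                f"feature dimension mismatch: {self.samples0.shape[1]} vs {self.samples1.shape[1]}"
            )
        if self.samples0.shape[0] < 2 or self.samples1.shape[0] < 2:
            raise ValueError("each class needs at least 2 samples")
        self.mean0 = self.samples0.mean(axis=0)
        self.mean1 = self.samples1.mean(axis=0)

    @property
    def n0(self) -> int:
        return self.samples0.shape[0]

    @property
    def n1(self) -> int:
        return self.samples1.shape[0]

    @property
    def dim(self) -> int:
        return self.samples0.shape[1]

    def second0(self, v: np.ndarray) -> np.ndarray:
        """``E[ZZ'] v`` over the class-0 sample."""
        return self.samples0.T @ (self.samples0 @ v) / self.n0

    def second1(self, v: np.ndarray) -> np.ndarray:
        """``E[YY'] v`` over the class-1 sample."""
        return self.samples1.T @ (self.samples1 @ v) / self.n1


@dataclass
class PairStream:
    """Pairing policy for the SqD expectation ``E[(Z - Y)(Z - Y)']``.

    ``independent_moments`` (default) expands the expectation under
    independent ``Z``, ``Y``:
    ``E[ZZ'] + E[YY'] - E[Z]E[Y]' - E[Y]E[Z]'`` — deterministic, no pairing
    noise.  ``sampled_pairs`` follows the streaming estimate: each sweep
    pairs every class-1 sample with a class-0 sample drawn with replacement
    (so every class-1 row is used once per sweep), re-drawn each sweep from
    a seeded generator.
    """

    pairing_policy: str = "independent_moments"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pairing_policy not in ("independent_moments", "sampled_pairs"):
            raise ValueError(f"unknown pairing policy {self.pairing_policy!r}")
        self._rng = np.random.default_rng(self.seed)

    def reset(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    def sweep_differences(self, moments: MomentSet) -> np.ndarray:
        """One sweep of sampled differences ``Z_sample - Y_j``, one row per class-1 sample."""
        idx = self._rng.integers(0, moments.n0, size=moments.n1)
        return moments.samples0[idx] - moments.samples1


def matvec(
    method: str,
    moments: MomentSet,
    v: np.ndarray,
    pairs: PairStream | None = None,
) -> np.ndarray:
    """Product of the objective matrix ``M`` for ``method`` with ``v``, matrix-free."""
    v = np.asarray(v, dtype=float)
    if not np.linalg.norm(v) > 0:
        raise ValueError("v must be nonzero")
    m0, m1 = moments.mean0, moments.mean1
    if method == "DS":
        return moments.second0(v) - moments.second1(v)
    if method == "VAR":
        return moments.second0(v) - moments.second1(v) - m0 * (m0 @ v) + m1 * (m1 @ v)
    if method == "TVM":
        d = m1 - m0
        return moments.second0(v) - moments.second1(v) + d * (m1 @ v) + m1 * (d @ v)
    if method == "SqD":
        policy = pairs.pairing_policy if pairs is not None else "independent_moments"
        if policy == "independent_moments":
            return (
                moments.second0(v)
                + moments.second1(v)
                - m0 * (m1 @ v)
                - m1 * (m0 @ v)
            )
        diffs = pairs.sweep_differences(moments)
        return diffs.T @ (diffs @ v) / diffs.shape[0]
    raise ValueError(f"unknown matvec method {method!r}")


def power_iteration(
    matvec_closure: Callable[[np.ndarray], np.ndarray],
    dim: int,
    tol: float = 1e-9,
    max_iter: int = 1000,
    _shifted: bool = False,
) -> tuple[np.ndarray, float, int, bool]:
    """Dominant eigenpair of a symmetric operator given only its matvec.

    Starts from the normalised all-ones vector and iterates
    ``u <- M u / ||M u||`` until ``1 - |u_k . u_{k-1}| < tol`` or
    ``max_iter`` steps.  Raw power iteration converges to the largest
    *magnitude* eigenvalue; since the filter objectives ask for the largest
    *algebraic* one on indefinite matrices, a converged negative dominant
    eigenvalue triggers a second run on the shifted operator
    ``M + |lambda| I``, whose dominant eigenpair is the algebraically
    largest of ``M``.  The returned eigenvalue is always the Rayleigh
    quotient ``u' M u`` of the original operator; the sign of ``u`` is fixed
    so its largest-magnitude component is positive (ties to the lowest
    index).

    Returns ``(u, eigenvalue, iterations, converged)``.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    u = np.ones(dim) / np.sqrt(dim)
    converged = False
    iterations = 0
    for k in range(1, max_iter + 1):
        w = matvec_closure(u)
        norm = np.linalg.norm(w)
        if norm == 0:
            if k == 1:
                raise DegenerateOperatorError(
                    "degenerate operator: matvec of the all-ones start vector is zero"
                )
            # u is (numerically) in the kernel; eigenvalue 0, keep u.
            iterations = k
            converged = True
            break
        u_next = w / norm
        iterations = k
        if 1.0 - abs(float(u @ u_next)) < tol:
            u = u_next
            converged = True
            break
        u = u_next
    lam = float(u @ matvec_closure(u))
    if converged and lam < 0 and not _shifted:
        shift = abs(lam)
        shifted = lambda x: matvec_closure(x) + shift * x
        u2, _, it2, conv2 = power_iteration(
            shifted, dim, tol=tol, max_iter=max_iter, _shifted=True
        )
        lam2 = float(u2 @ matvec_closure(u2))
        return _fix_sign(u2), lam2, iterations + it2, conv2
    return _fix_sign(u), lam, iterations, converged


def _fix_sign(u: np.ndarray) -> np.ndarray:
    idx = int(np.argmax(np.abs(u)))
    return -u if u[idx] < 0 else u


# ---------------------------------------------------------------------------
# Filter banks


@dataclass
class FilterWeights:
    """A bank of per-(channel, band) weight vectors plus eigen metadata.

    ``weights`` maps ``"<channel>:<band>"`` (per-channel scope) or
    ``"joint:<band>"`` (one filter over the concatenated channels) to the
    weight vector over that band's bins.  Supervised vectors are unit norm;
    PBF weights are the uniform average ``1/m``.  ``info`` carries
    ``(eigenvalue, iterations, converged)`` for the power-iteration methods.
    """

    method: str
    scope: str
    sampling_rate_hz: float
    fft_length: int
    n_channels: int
    band_names: list[str]
    band_ranges: dict[str, tuple[int, int]]
    weights: dict[str, np.ndarray]
    info: dict[str, dict] = field(default_factory=dict)

    def key(self, channel: int | str, band: str) -> str:
        return f"{channel}:{band}"

    def vector(self, channel: int | str, band: str) -> np.ndarray:
        return self.weights[self.key(channel, band)]

    @property
    def n_columns(self) -> int:
        """Feature columns produced by apply_filters."""
        nb = len(self.band_names)
        return nb if self.scope == "joint" else self.n_channels * nb

    def column_names(self) -> list[str]:
        if self.scope == "joint":
            return [f"joint:{b}" for b in self.band_names]
        return [f"ch{c}:{b}" for c in range(self.n_channels) for b in self.band_names]

    def to_json(self, path) -> None:
        payload = {
            "method": self.method,
            "scope": self.scope,
            "sampling_rate_hz": self.sampling_rate_hz,
            "fft_length": self.fft_length,
            "n_channels": self.n_channels,
            "band_names": self.band_names,
            "band_ranges": {k: list(v) for k, v in self.band_ranges.items()},
            "weights": {k: v.tolist() for k, v in self.weights.items()},
            "info": self.info,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "FilterWeights":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            method=payload["method"],
            scope=payload["scope"],
            sampling_rate_hz=payload["sampling_rate_hz"],
            fft_length=payload["fft_length"],
            n_channels=payload["n_channels"],
            band_names=list(payload["band_names"]),
            band_ranges={k: tuple(v) for k, v in payload["band_ranges"].items()},
            weights={k: np.asarray(v, dtype=float) for k, v in payload["weights"].items()},
            info=payload.get("info", {}),
        )


def _stack_values(spectra: Sequence[SpectralTensor] | SpectralTensor) -> np.ndarray:
    if isinstance(spectra, SpectralTensor):
        return spectra.values
    if not spectra:
        raise ValueError("empty spectra collection")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.fft_length != ref.fft_length or s.sampling_rate_hz != ref.sampling_rate_hz:
            raise ValueError("spectra collection mixes FFT geometries")
    return np.concatenate([s.values for s in spectra], axis=0)


def _band_samples(values: np.ndarray, channel: int | None, sl: slice) -> np.ndarray:
    """Window-level sample matrix for one band: per-channel slice or channel-concatenated."""
    if channel is not None:
        return values[:, channel, sl]
    return values[:, :, sl].reshape(values.shape[0], -1)


def estimate_single(
    method: str,
    features0: np.ndarray,
    features1: np.ndarray,
    pairing: PairStream | None = None,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> tuple[np.ndarray, dict]:
    """One weight vector from two window-level sample matrices (rows = windows)."""
    d = features0.shape[1]
    if method == "PBF":
        return np.full(d, 1.0 / d), {}
    if method == "DM":
        diff = features0.mean(axis=0) - features1.mean(axis=0)
        norm = np.linalg.norm(diff)
        if norm == 0:
            raise DegenerateOperatorError("DM: class means are identical")
        return diff / norm, {}
    moments = MomentSet(features0, features1)
    if method == "SqD" and pairing is not None:
        pairing.reset()
    closure = lambda v: matvec(method, moments, v, pairs=pairing)
    u, lam, iters, converged = power_iteration(closure, d, tol=tol, max_iter=max_iter)
    return u, {"eigenvalue": lam, "iterations": iters, "converged": bool(converged)}


def estimate_filter(
    method: str,
    spectra0: Sequence[SpectralTensor] | SpectralTensor,
    spectra1: Sequence[SpectralTensor] | SpectralTensor,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
    scope: str = "per_channel",
    pairing: PairStream | None = None,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> FilterWeights:
    """Estimate a filter bank from labeled training spectra.

    Every analysis window of every training clip contributes one sample of
    its clip's class; class 0 is interictal (``spectra0``), class 1
    preictal.  With ``scope='per_channel'`` a separate filter is fitted for
    each (channel, band); with ``'joint'`` one filter per band spans the
    concatenated channels.
    """
    if method not in ALL_METHODS:
        raise ValueError(f"unknown method {method!r}; pick from {ALL_METHODS}")
    if scope not in ("per_channel", "joint"):
        raise ValueError(f"unknown scope {scope!r}")
    v0, v1 = _stack_values(spectra0), _stack_values(spectra1)
    ref = spectra0 if isinstance(spectra0, SpectralTensor) else spectra0[0]
    if v0.shape[1:] != v1.shape[1:]:
        raise ValueError("class spectra have different (channels, bins) shapes")
    ranges = band_bin_ranges(ref.sampling_rate_hz, ref.fft_length, bands)
    nonempty = {n: s for n, s in ranges.items() if s.stop > s.start}
    if not nonempty:
        raise ValueError("all bands empty at this sampling rate")
    n_channels = v0.shape[1]
    channels: list[int | None] = [None] if scope == "joint" else list(range(n_channels))
    weights: dict[str, np.ndarray] = {}
    info: dict[str, dict] = {}
    for band_name, sl in nonempty.items():
        for channel in channels:
            f0 = _band_samples(v0, channel, sl)
            f1 = _band_samples(v1, channel, sl)
            u, meta = estimate_single(method, f0, f1, pairing, tol, max_iter)
            key = f"{'joint' if channel is None else channel}:{band_name}"
            weights[key] = u
            if meta:
                info[key] = meta
    return FilterWeights(
        method=method,
        scope=scope,
        sampling_rate_hz=ref.sampling_rate_hz,
        fft_length=ref.fft_length,
        n_channels=n_channels,
        band_names=list(nonempty),
        band_ranges={n: (s.start, s.stop) for n, s in nonempty.items()},
        weights=weights,
        info=info,
    )


def apply_filters(spectra: SpectralTensor, weights: FilterWeights) -> np.ndarray:
    """Reduce a spectral tensor to band-filtered features, one row per window.

    Per-channel scope yields ``channels x bands`` columns ordered
    channel-major, band-minor (``ch0:delta, ch0:theta, ..., ch1:delta, ...``);
    joint scope yields one column per band.  If the tensor carries raw
    (uncompressed) magnitudes, log1p is applied to the filtered outputs
    here, after clamping to the domain of log1p.
    """
    if spectra.fft_length != weights.fft_length or spectra.sampling_rate_hz != weights.sampling_rate_hz:
        raise ValueError(
            "spectra geometry (rate, fft_length) does not match the filter bank"
        )
    if weights.scope == "per_channel" and spectra.n_channels != weights.n_channels:
        raise ValueError(
            f"channel mismatch: spectra {spectra.n_channels}, filters {weights.n_channels}"
        )
    n_w = spectra.n_windows
    out = np.empty((n_w, weights.n_columns))
    col = 0
    if weights.scope == "joint":
        for band in weights.band_names:
            start, stop = weights.band_ranges[band]
            block = spectra.values[:, :, start:stop].reshape(n_w, -1)
            out[:, col] = block @ weights.weights[f"joint:{band}"]
            col += 1
    else:
        for channel in range(weights.n_channels):
            for band in weights.band_names:
                start, stop = weights.band_ranges[band]
                out[:, col] = spectra.values[:, channel, start:stop] @ weights.vector(channel, band)
                col += 1
    if not spectra.log_applied:
        out = np.log1p(np.clip(out, -1.0 + 1e-12, None))
    return out
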