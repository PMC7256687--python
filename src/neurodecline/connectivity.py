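"""MVAR-based frequency-domain interaction measures.

Each 1 s EEG segment is modelled as an order-10 multivariate autoregressive
(MVAR) process

    x(t) = sum_{k=1..p} A_k x(t-k) + e(t),   Cov e = Sigma.

The coefficient polynomial on the frequency grid,
``Abar(f) = I - sum_k A_k exp(-2*pi*i*f*k/fs)``, its inverse (the transfer
function ``H``), and the spectral matrix ``S = H Sigma H^H`` yield the
classical directed and undirected interaction measures: coherence,
partial coherence, the partial-directed-coherence family (PDC, PDCF,
gPDC), the directed-transfer-function family (DTF, ffDTF, dDTF) and
Geweke-Granger causality.  Measures are averaged into six classical
frequency bands and flattened to nonredundant feature vectors.

The MVAR estimator is a Vieira-Morf lattice (partial-correlation)
recursion with unbiased covariance normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

logger = logging.getLogger(__name__)

#: Classical EEG frequency bands, closed integer ranges in Hz.
BANDS: dict[str, tuple[int, int]] = {
    "delta": (2, 4),
    "theta": (5, 7),
    "alpha": (8, 13),
    "beta": (14, 30),
    "gamma": (31, 80),
    "high_gamma": (81, 125),
}

DEFAULT_FREQS = np.arange(2, 126, dtype=float)  # 1 Hz steps, 124 points

#: measure name -> (directed?, complex-banded?)  Directed measures keep all
#: ordered off-diagonal pairs; symmetric ones the upper triangle.
MEASURES: dict[str, dict] = {
    "spectrum": {"directed": False, "diagonal": True},
    "coherence_complex": {"directed": False, "diagonal": False, "complex": True},
    "coherence_real": {"directed": False, "diagonal": False},
    "coherence_imag": {"directed": False, "diagonal": False},
    "pCOH": {"directed": False, "diagonal": False},
    "PDC": {"directed": True, "diagonal": False},
    "PDCF": {"directed": True, "diagonal": False},
    "gPDC": {"directed": True, "diagonal": False},
    "DTF": {"directed": True, "diagonal": False},
    "dDTF": {"directed": True, "diagonal": False},
    "ffDTF": {"directed": True, "diagonal": False},
    "GGC": {"directed": True, "diagonal": False},
    "direct_causality": {"directed": True, "diagonal": False},
    "transfer_function": {"directed": True, "diagonal": False},
    "tf_polynomial": {"directed": True, "diagonal": False},
}


class MVARStabilityError(RuntimeError):
    """Raised when a coefficient set describes an unstable process."""


@dataclass
class MVARModel:
    """Fitted MVAR model: coefficients ``coeffs[k-1] = A_k`` and noise cov."""

    coeffs: np.ndarray  # (p, m, m)
    sigma: np.ndarray  # (m, m), µV²
    fs: float

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        p, m, _ = self.coeffs.shape
        comp = np.zeros((p * m, p * m))
        comp[:m] = np.concatenate(list(self.coeffs), axis=1)
        if p > 1:
            comp[m:, : (p - 1) * m] = np.eye((p - 1) * m)
        return comp

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0


@dataclass
class SpectralSet:
    """Ā(f), H(f) = Ā(f)^-1 and S(f) = H Σ Hᴴ on a frequency grid."""

    freqs: np.ndarray  # (nf,)
    abar: np.ndarray  # (nf, m, m) complex
    transfer: np.ndarray  # (nf, m, m) complex
    spectrum: np.ndarray  # (nf, m, m) complex Hermitian
    sigma: np.ndarray  # (m, m)
    fs: float


def _chol_psd(a: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, with minimal jitter for near-singular input."""
    try:
        return cholesky(a, lower=True)
    except np.linalg.LinAlgError:
        eps = 1e-12 * max(np.trace(a) / len(a), 1e-30)
        for _ in range(8):
            try:
                return cholesky(a + eps * np.eye(len(a)), lower=True)
            except np.linalg.LinAlgError:
                eps *= 100.0
        raise


def fit_mvar(data: np.ndarray, order: int = 10, fs: float = 1.0) -> MVARModel:
    """Fit an MVAR model with the Vieira-Morf lattice recursion.

    Partial-correlation (lattice) estimation with unbiased ``1/(n - k)``
    covariance scaling at each lag.  The channel means are removed first.

    Parameters
    ----------
    data : (n_channels, n_samples) array
    order : model order p (default 10)
    fs : sampling rate carried into spectral evaluation
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    if n <= order:
        raise ValueError("need more samples than the model order")
    dead = np.flatnonzero(np.ptp(x, axis=1) == 0)
    if dead.size:
        raise ValueError(f"constant (rank-deficient) channel index {dead[0]}")
    x = x - x.mean(axis=1, keepdims=True)

    f = x.copy()  # forward prediction error
    b = x.copy()  # backward prediction error
    arf = np.zeros((order, m, m))  # forward AR coefficients A_k
    arb = np.zeros((order, m, m))  # backward counterparts

    for k in range(1, order + 1):
        nk = n - k
        fk = f[:, k:]
        bk = b[:, k - 1 : n - 1]
        # stage covariances over the aligned sample range, unbiased 1/(n-k);
        # recomputing them empirically keeps the normalised reflection
        # coefficient a true correlation (singular values <= 1)
        pef = fk @ fk.T / nk
        peb = bk @ bk.T / nk
        delta = fk @ bk.T / nk
        lf = _chol_psd(pef)
        lb = _chol_psd(peb)
        # normalised partial correlation (geometric-mean normalisation)
        rho = solve_triangular(lf, delta, lower=True)
        rho = solve_triangular(lb, rho.T, lower=True).T
        kf = lf @ rho @ np.linalg.inv(lb)  # forward reflection coefficient
        kb = lb @ rho.conj().T @ np.linalg.inv(lf)

        f = np.concatenate(
            [f[:, :k], fk - kf @ bk], axis=1
        )
        b = np.concatenate(
            [b[:, : k - 1], np.zeros((m, 1)), bk - kb @ fk], axis=1
        )

        arf_new = arf.copy()
        arb_new = arb.copy()
        arf_new[k - 1] = kf
        arb_new[k - 1] = kb
        for i in range(k - 1):
            arf_new[i] = arf[i] - kf @ arb[k - 2 - i]
            arb_new[i] = arb[i] - kb @ arf[k - 2 - i]
        arf, arb = arf_new, arb_new

    ff = f[:, order:]
    sigma = ff @ ff.T / (n - order)
    sigma = 0.5 * (sigma + sigma.T)
    model = MVARModel(coeffs=arf, sigma=sigma, fs=fs)
    if not model.is_stable():
        logger.warning("fitted MVAR model is unstable (spectral radius >= 1)")
    return model


def residuals(model: MVARModel, data: np.ndarray) -> np.ndarray:
    """One-step-ahead prediction errors of ``data`` under ``model``."""
    x = np.asarray(data, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    p = model.order
    n = x.shape[1]
    pred = np.zeros_like(x[:, p:])
    for k in range(1, p + 1):
        pred += model.coeffs[k - 1] @ x[:, p - k : n - k]
    return x[:, p:] - pred


def spectral_set(
    model: MVARModel, freqs: np.ndarray | None = None, fs: float | None = None
) -> SpectralSet:
    """Evaluate Ā, H and S on the frequency grid (default 2..125 Hz, 1 Hz)."""
    if freqs is None:
        freqs = DEFAULT_FREQS
    fs = float(fs if fs is not None else model.fs)
    p, m, _ = model.coeffs.shape
    freqs = np.asarray(freqs, dtype=float)
    k = np.arange(1, p + 1)
    # phase factors: (nf, p)
    z = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)
    abar = np.tile(np.eye(m, dtype=complex), (len(freqs), 1, 1))
    abar -= np.einsum("fk,kij->fij", z, model.coeffs.astype(complex))
    try:
        transfer = np.linalg.inv(abar)
    except np.linalg.LinAlgError:
        bad = [f for f, a in zip(freqs, abar) if np.linalg.matrix_rank(a) < m]
        raise np.linalg.LinAlgError(
            f"singular coefficient polynomial at frequency {bad[:1]}"
        )
    spectrum = transfer @ model.sigma @ transfer.conj().transpose(0, 2, 1)
    return SpectralSet(
        freqs=freqs, abar=abar, transfer=transfer, spectrum=spectrum,
        sigma=model.sigma, fs=fs,
    )


def _partial_coherence(sset: SpectralSet, ridge: float = 0.0) -> np.ndarray:
    s = sset.spectrum
    m = s.shape[-1]
    try:
        p = np.linalg.inv(s)
    except np.linalg.LinAlgError:
        eps = ridge or 1e-10 * np.abs(np.trace(s, axis1=1, axis2=2)).mean() / m
        logger.warning("singular spectral matrix; ridge-regularising with %g", eps)
        p = np.linalg.inv(s + eps * np.eye(m))
    d = np.sqrt(np.abs(np.einsum("fii->fi", p)))
    return -p / (d[:, :, None] * d[:, None, :])


def compute_measure(sset: SpectralSet, name: str) -> np.ndarray:
    """One interaction measure as a (n_freqs, m, m) tensor.

    Conventions: entry ``[f, i, j]`` quantifies influence from source ``j``
    to target ``i`` for directed measures, and the (i, j) pair for
    symmetric ones.  Normalised squared measures lie in [0, 1]; PDC is
    column-normalised, DTF row-normalised.
    """
    if name not in MEASURES:
        raise ValueError(f"unknown measure {name!r}")
    s = sset.spectrum
    h = sset.transfer
    abar = sset.abar
    sigma = sset.sigma

    if name == "spectrum":
        return s.copy()
    if name in ("coherence_complex", "coherence_real", "coherence_imag"):
        d = np.sqrt(np.abs(np.einsum("fii->fi", s)))
        coh = s / (d[:, :, None] * d[:, None, :])
        if name == "coherence_real":
            return coh.real.copy()
        if name == "coherence_imag":
            return coh.imag.copy()
        return coh
    if name == "pCOH":
        return np.abs(_partial_coherence(sset))
    if name == "PDC":
        denom = np.sqrt(np.sum(np.abs(abar) ** 2, axis=1, keepdims=True))
        return np.abs(abar) / denom
    if name == "PDCF":
        sig_inv = np.linalg.inv(sigma)
        # a_j^H Sigma^-1 a_j per column j
        denom = np.sqrt(
            np.abs(np.einsum("fkj,kl,flj->fj", abar.conj(), sig_inv, abar))
        )
        return np.abs(abar) / denom[:, None, :]
    if name == "gPDC":
        w = 1.0 / np.sqrt(np.diag(sigma))  # 1/sigma_ii
        num = np.abs(abar) * w[None, :, None]
        denom = np.sqrt(np.sum(num**2, axis=1, keepdims=True))
        return num / denom
    if name == "DTF":
        denom = np.sqrt(np.sum(np.abs(h) ** 2, axis=2, keepdims=True))
        return np.abs(h) / denom
    if name == "ffDTF":
        denom = np.sqrt(np.sum(np.abs(h) ** 2, axis=(0, 2)))  # per target row i
        return np.abs(h) / denom[None, :, None]
    if name in ("dDTF", "direct_causality"):
        ff = compute_measure(sset, "ffDTF")
        return ff * np.abs(_partial_coherence(sset))
    if name == "GGC":
        s_ii = np.abs(np.einsum("fii->fi", s))  # (nf, m)
        sig_d = np.diag(sigma)
        # partialised innovation variance of source j w.r.t. target i
        resid = sig_d[None, :] - sigma**2 / sig_d[:, None]  # (i, j)
        num = resid[None, :, :] * np.abs(h) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.log(s_ii[:, :, None] / np.maximum(s_ii[:, :, None] - num, 1e-300))
        return np.clip(out, 0.0, None)
    if name == "transfer_function":
        return np.abs(h)
    if name == "tf_polynomial":
        return np.abs(abar)
    raise AssertionError("unreachable")


def band_average(
    freq_tensor: np.ndarray,
    freqs: np.ndarray,
    bands: dict[str, tuple[int, int]] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Arithmetic mean over the integer frequencies of each closed band.

    Complex input is averaged component-wise (real and imaginary parts
    separately); all other measures are real by construction here.
    """
    if bands is None:
        bands = BANDS
    names = list(bands)
    out = np.empty((len(names),) + freq_tensor.shape[1:], dtype=freq_tensor.dtype)
    for bi, bname in enumerate(names):
        lo, hi = bands[bname]
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(f"frequency grid does not cover band {bname}")
        out[bi] = freq_tensor[sel].mean(axis=0)
    return out, names


def vectorize(
    band_tensor: np.ndarray,
    measure: str,
    channel_names: list[str],
    band_names: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Flatten a band x m x m tensor to its nonredundant entries.

    Symmetric measures keep the upper triangle (the spectrum also keeps the
    diagonal, i.e. the auto-spectra); directed measures keep every ordered
    off-diagonal pair.  Complex entries are emitted as (real, imag) pairs.
    Identifiers follow ``measure:band:source->target`` for directed
    measures and ``measure:band:a<->b`` for symmetric ones.
    """
    info = MEASURES[measure]
    band_names = band_names or list(BANDS)
    m = band_tensor.shape[-1]
    values: list[float] = []
    ids: list[str] = []
    for bi, bname in enumerate(band_names):
        mat = band_tensor[bi]
        if info["directed"]:
            pairs = [(i, j) for j in range(m) for i in range(m) if i != j]
        else:
            lo = 0 if info["diagonal"] else 1
            pairs = [(i, j) for i in range(m) for j in range(i + lo, m)]
        for i, j in pairs:
            v = mat[i, j]
            if info["directed"]:
                pid = f"{measure}:{bname}:{channel_names[j]}->{channel_names[i]}"
            else:
                pid = f"{measure}:{bname}:{channel_names[i]}<->{channel_names[j]}"
            if info.get("complex"):
                values.extend([v.real, v.imag])
                ids.extend([pid + ":re", pid + ":im"])
            else:
                values.append(float(np.real(v)))
                ids.append(pid)
    return np.asarray(values), ids


def segment_features(
    segments,
    measures: list[str] | None = None,
    order: int = 10,
    freqs: np.ndarray | None = None,
    bands: dict[str, tuple[int, int]] | None = None,
    channel_names: list[str] | None = None,
) -> pd.DataFrame:
    """Connectivity feature table: one row per segment.

    Fits one MVAR model per segment (no averaging across segments), derives
    the requested measures, band-averages and flattens them, and prefixes
    metadata columns ``participant_id``, ``condition``, ``session``.
    """
    if measures is None:
        measures = ["PDC"]
    rows = []
    meta = []
    ids: list[str] | None = None
    for seg in segments:
        fs = seg.data.shape[1]  # segments are 1 s long by construction
        model = fit_mvar(seg.data, order=order, fs=fs)
        sset = spectral_set(model, freqs=freqs)
        chn = channel_names or [f"ch{i}" for i in range(seg.data.shape[0])]
        vec_parts, id_parts = [], []
        for mname in measures:
            tensor = compute_measure(sset, mname)
            banded, bnames = band_average(tensor, sset.freqs, bands)
            v, fids = vectorize(banded, mname, chn, bnames)
            vec_parts.append(v)
            id_parts.extend(fids)
        if ids is None:
            ids = id_parts
        rows.append(np.concatenate(vec_parts))
        meta.append((seg.participant_id, seg.condition, seg.session))
    if not rows:
        raise ValueError("no segments supplied")
    df = pd.DataFrame(rows, columns=ids)
    df.insert(0, "session", [m[2] for m in meta])
    df.insert(0, "condition", [m[1] for m in meta])
    df.insert(0, "participant_id", [m[0] for m in meta])
    return df
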