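"""State-conditioned spectral characterization.

Multitaper PSD and coherence computed on 2-s Slepian-tapered windows
assigned to whichever state dominates them, non-negative matrix
factorization of stacked coherence spectra into common frequency
modes, parameterization of each PSD into an aperiodic (1/f) component
plus up to a few Gaussian peaks, selection of the individual alpha
peak (7-14 Hz, lowest in-band peak wins), and selection of a network's
critical nodes as the endpoints of its strongest alpha-band coherence
edges.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal.windows import dpss
from sklearn.decomposition import NMF

__all__ = [
    "StateSpectra",
    "SpectralFit",
    "AlphaDefinition",
    "state_multitaper",
    "nnmf_bands",
    "fit_spectral_model",
    "select_alpha_peak",
    "select_critical_nodes",
]


@dataclasses.dataclass
class StateSpectra:
    """Per-state multitaper spectra on a common frequency grid."""

    freqs: np.ndarray  # Hz
    psd: np.ndarray  # states x parcels x freqs, NaN where state absent
    coherence: np.ndarray  # states x parcels x parcels x freqs, in [0, 1]
    n_windows: np.ndarray  # windows assigned per state


@dataclasses.dataclass
class SpectralFit:
    """Aperiodic + periodic decomposition of one log-power spectrum."""

    offset: float
    exponent: float
    peaks: list  # (center_freq Hz, height above aperiodic, bandwidth Hz)
    r_squared: float

    def aperiodic(self, freqs: np.ndarray) -> np.ndarray:
        """Aperiodic component in log10 power units."""
        return self.offset - self.exponent * np.log10(freqs)


@dataclasses.dataclass
class AlphaDefinition:
    """Per subject x state alpha center frequency and critical nodes."""

    center_freq: np.ndarray  # subjects x states, Hz
    source: np.ndarray  # subjects x states: "fitted" | "group-fallback"
    critical_nodes: dict | None = None  # state -> parcel indices


def state_multitaper(
    ts,
    state_path,
    n_states: int | None = None,
    window_s: float = 2.0,
    n_tapers: int = 7,
    fmin: float = 1.0,
    fmax: float = 45.0,
    min_window_fraction: float = 0.5,
):
    """State-conditioned multitaper PSD and coherence.

    The recording is cut into non-overlapping ``window_s`` segments and
    a segment is assigned to state k when at least
    ``min_window_fraction`` of its samples carry Viterbi label k.  Seven
    Slepian tapers over 2-s windows (time-halfbandwidth NW = 4) give a
    0.5 Hz grid with +/-2 Hz smoothing.  Coherence is
    |S_ij|^2 / (S_ii S_jj) after averaging cross-spectra over tapers
    and segments.  A state owning no segment gets NaN spectra and a
    warning.
    """
    data, fs = (ts.data, ts.fs) if hasattr(ts, "data") else (np.asarray(ts), None)
    if fs is None:
        raise ValueError("pass a ParcelTimeSeries (sampling rate required)")
    state_path = np.asarray(state_path)
    if state_path.ndim == 2:  # gammas passed: use hard argmax labels
        state_path = state_path.argmax(axis=1)
    if n_states is None:
        n_states = int(state_path.max()) + 1
    n_parcels, n_samples = data.shape
    nwin = int(round(window_s * fs))
    n_segments = n_samples // nwin
    if n_segments < 2:
        raise ValueError("recording must cover at least two windows")
    nw = (n_tapers + 1) / 2.0  # 7 tapers -> NW = 4
    tapers = dpss(nwin, nw, Kmax=n_tapers)  # unit-energy rows
    freqs = np.fft.rfftfreq(nwin, 1.0 / fs)
    fsel = (freqs >= fmin) & (freqs <= fmax)
    freqs_out = freqs[fsel]

    segs = data[:, : n_segments * nwin].reshape(n_parcels, n_segments, nwin)
    labels = state_path[: n_segments * nwin].reshape(n_segments, nwin)
    # taper, FFT: (segments, tapers, parcels, freqs)
    tapered = segs[:, :, None, :] * tapers[None, None, :, :]
    fftc = np.fft.rfft(tapered, axis=-1)[..., fsel]
    fftc = np.moveaxis(fftc, 0, 2)  # -> (segments, tapers, parcels, freqs)
    scale = 2.0 / fs  # one-sided density; tapers are unit-energy

    psd = np.full((n_states, n_parcels, freqs_out.size), np.nan)
    coh = np.full((n_states, n_parcels, n_parcels, freqs_out.size), np.nan)
    n_windows = np.zeros(n_states, dtype=int)
    for k in range(n_states):
        frac = (labels == k).mean(axis=1)
        sel = frac >= min_window_fraction
        n_windows[k] = int(sel.sum())
        if not sel.any():
            warnings.warn(f"state {k} owns no {window_s:g}-s window; "
                          "spectra set to missing")
            continue
        Xk = fftc[sel]  # n_sel x tapers x parcels x freqs
        S = np.einsum("wtpf,wtqf->pqf", Xk, np.conj(Xk)) * (
            scale / (sel.sum() * tapers.shape[0])
        )
        p_auto = np.real(np.einsum("ppf->pf", S))
        psd[k] = p_auto
        denom = p_auto[:, None, :] * p_auto[None, :, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            coh[k] = np.abs(S) ** 2 / denom
        coh[k] = np.clip(coh[k], 0.0, 1.0)
    return StateSpectra(freqs=freqs_out, psd=psd, coherence=coh,
                        n_windows=n_windows)


def nnmf_bands(
    coherence_stack: np.ndarray, n_modes: int = 2, seed: int = 0
):
    """Factorize stacked coherence spectra into common frequency modes.

    ``coherence_stack`` is observations x frequencies (rows are
    subject/state/edge coherence spectra).  Returns ``(weights, modes,
    reconstruction_error)`` with modes as rows over frequency.  The
    deterministic NNDSVD-A initialization plus the seed make repeated
    calls reproducible.
    """
    V = np.asarray(coherence_stack, float)
    if np.any(V < 0):
        raise ValueError("coherence spectra must be non-negative")
    if not np.any(V > 0):
        raise ValueError("all-zero input cannot be factorized")
    model = NMF(
        n_components=n_modes,
        init="nndsvda",
        random_state=seed,
        max_iter=5000,
        tol=1e-7,
    )
    W = model.fit_transform(V)
    H = model.components_
    err = float(model.reconstruction_err_)
    # order modes by their peak frequency index for stable downstream use
    order = np.argsort(H.argmax(axis=1))
    return W[:, order], H[order], err


# ---------------------------------------------------------------------------
# spectral parameterization (aperiodic + Gaussian peaks on log10 power)


def _gaussian(f, cf, height, sd):
    return height * np.exp(-0.5 * ((f - cf) / sd) ** 2)


def _drop_overlapping(peaks, fwhm_to_sd, factor: float = 0.75):
    """Keep only the tallest of mutually overlapping peaks.

    Two Gaussians overlap when their centers are within ``factor``
    times the sum of their SDs — a shoulder artifact of a dominant
    peak, not a separate oscillation.
    """
    kept = []
    for cf, h, fw in sorted(peaks, key=lambda p: -p[1]):
        sd = fw * fwhm_to_sd
        if all(
            abs(cf - cf2) > factor * (sd + fw2 * fwhm_to_sd)
            for cf2, _, fw2 in kept
        ):
            kept.append((cf, h, fw))
    return kept


def _robust_aperiodic_fit(freqs, logpsd, percentile: float = 25.0):
    """Fit offset - exponent*log10(f), down-weighting peak regions.

    First pass: ordinary least squares.  Second pass: refit on the
    quartile of points closest to the first-pass line from below,
    which strips oscillatory peaks from the aperiodic estimate.
    """
    logf = np.log10(freqs)
    A = np.c_[np.ones_like(logf), -logf]
    coef, *_ = np.linalg.lstsq(A, logpsd, rcond=None)
    resid = logpsd - A @ coef
    flat = resid - resid.min()
    thresh = np.percentile(flat, percentile)
    keep = flat <= thresh
    if keep.sum() >= 2:
        coef, *_ = np.linalg.lstsq(A[keep], logpsd[keep], rcond=None)
    return coef  # (offset, exponent)


def fit_spectral_model(
    psd: np.ndarray,
    freqs: np.ndarray,
    peak_width_limits: tuple[float, float] = (0.2, 12.0),
    max_n_peaks: int = 3,
    min_peak_height: float = 0.3,
    peak_threshold: float = 2.0,
    fmin: float = 1.0,
    fmax: float = 45.0,
) -> SpectralFit:
    """Parameterize a PSD into aperiodic and periodic components.

    Works on log10 power over ``fmin``-``fmax``: a fixed (no-knee)
    aperiodic component ``offset - exponent*log10(f)`` plus up to
    ``max_n_peaks`` Gaussians extracted iteratively from the flattened
    spectrum.  A candidate peak must rise above both ``min_peak_height``
    (log10 units) and ``peak_threshold`` standard deviations of the
    flattened spectrum; fitted peaks are kept only within the FWHM
    ``peak_width_limits`` (Hz) and are returned sorted by center
    frequency.
    """
    psd = np.asarray(psd, float)
    freqs = np.asarray(freqs, float)
    if not np.all(np.isfinite(psd)):
        raise ValueError("psd contains non-finite values")
    sel = (freqs >= fmin) & (freqs <= fmax) & (freqs > 0)
    f = freqs[sel]
    if np.any(psd[sel] <= 0):
        raise ValueError("psd must be strictly positive on the fit range")
    logp = np.log10(psd[sel])

    fwhm_to_sd = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sd_lo = peak_width_limits[0] * fwhm_to_sd
    sd_hi = peak_width_limits[1] * fwhm_to_sd
    logf = np.log10(f)
    A = np.c_[np.ones_like(logf), -logf]

    def extract_peaks(flat):
        """Iterative tallest-first Gaussian extraction + joint refit."""
        guesses = []
        resid = flat.copy()
        for _ in range(max_n_peaks):
            i = int(np.argmax(resid))
            height = resid[i]
            if (height < min_peak_height
                    or height < peak_threshold * resid.std()):
                break
            half = height / 2.0
            li = i
            while li > 0 and resid[li] > half:
                li -= 1
            ri = i
            while ri < resid.size - 1 and resid[ri] > half:
                ri += 1
            fwhm = max(f[ri] - f[li], f[1] - f[0])
            sd = np.clip(fwhm * fwhm_to_sd, sd_lo, sd_hi)
            guesses.append((f[i], height, sd))
            resid = resid - _gaussian(f, f[i], height, sd)
        if not guesses:
            return []

        def model(fx, *params):
            out = np.zeros_like(fx)
            for j in range(len(params) // 3):
                out += _gaussian(fx, *params[3 * j : 3 * j + 3])
            return out

        p0 = np.ravel(guesses)
        lo = np.tile([f[0], 0.0, sd_lo], len(guesses))
        hi = np.tile([f[-1], np.inf, sd_hi], len(guesses))
        try:
            popt, _ = curve_fit(model, f, flat, p0=p0, bounds=(lo, hi),
                                maxfev=5000)
        except RuntimeError:
            popt = p0
        peaks = []
        for j in range(len(guesses)):
            cf, height, sd = popt[3 * j : 3 * j + 3]
            fwhm = sd / fwhm_to_sd
            if height < min_peak_height:
                continue
            if not (peak_width_limits[0] <= fwhm <= peak_width_limits[1]):
                continue
            peaks.append((float(cf), float(height), float(fwhm)))
        return _drop_overlapping(peaks, fwhm_to_sd)

    # alternate aperiodic and periodic fits: the robust first pass is
    # refined by refitting the aperiodic line on the peak-removed
    # spectrum, then re-extracting peaks from the cleaner flattening
    offset, exponent = _robust_aperiodic_fit(f, logp)
    peaks = []
    for _ in range(2):
        peaks = extract_peaks(logp - (offset - exponent * logf))
        peak_sum = np.zeros_like(f)
        for cf, height, fwhm in peaks:
            peak_sum += _gaussian(f, cf, height, fwhm * fwhm_to_sd)
        (offset, exponent), *_ = np.linalg.lstsq(
            A, logp - peak_sum, rcond=None
        )
    peaks.sort(key=lambda p: p[0])

    peak_sum = np.zeros_like(f)
    for cf, height, fwhm in peaks:
        peak_sum += _gaussian(f, cf, height, fwhm * fwhm_to_sd)
    fitted = offset - exponent * logf + peak_sum
    ss_res = np.sum((logp - fitted) ** 2)
    ss_tot = np.sum((logp - logp.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SpectralFit(float(offset), float(exponent), peaks, float(r2))


def select_alpha_peak(
    fits,
    band: tuple[float, float] = (7.0, 14.0),
    group_fallback: bool = True,
) -> AlphaDefinition:
    """Individual alpha center frequency per subject x state.

    ``fits`` is a subjects x states nested sequence of ``SpectralFit``.
    The CF is the fitted peak center inside ``band`` (the lowest one if
    several fall in band); a subject/state with no in-band peak gets
    the group mean of the fitted CFs for that state, flagged
    ``group-fallback``.  If no subject has an in-band peak for some
    state the fallback is undefined and an error is raised.
    """
    n_subj = len(fits)
    n_states = len(fits[0])
    cf = np.full((n_subj, n_states), np.nan)
    source = np.full((n_subj, n_states), "fitted", dtype=object)
    for s in range(n_subj):
        for k in range(n_states):
            in_band = [
                p[0]
                for p in fits[s][k].peaks
                if band[0] <= p[0] <= band[1]
            ]
            if in_band:
                cf[s, k] = min(in_band)
    for k in range(n_states):
        fitted = cf[:, k][np.isfinite(cf[:, k])]
        missing = np.isnan(cf[:, k])
        if missing.any():
            if not group_fallback or fitted.size == 0:
                raise ValueError(
                    f"no subject has an in-band alpha peak for state {k}; "
                    "group fallback undefined"
                )
            cf[missing, k] = fitted.mean()
            source[missing, k] = "group-fallback"
    return AlphaDefinition(center_freq=cf, source=source)


def select_critical_nodes(
    coherence: np.ndarray, edge_fraction: float = 0.0025
) -> np.ndarray:
    """Critical nodes: endpoints of the strongest alpha-band edges.

    ``coherence`` is a symmetric parcels x parcels matrix (already
    collapsed over the alpha band).  The top ``edge_fraction`` of the
    parcel-pair edges are taken (at least one edge; a warning is logged
    when the fraction rounds to zero edges) and the node set is the
    union of their endpoints.  At the default 0.25% on 52 parcels this
    is the top ~3 of 1326 edges, i.e. 6-7 nodes per network.
    """
    C = np.asarray(coherence, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("coherence must be a square matrix")
    if not np.allclose(C, C.T, atol=1e-8, equal_nan=True):
        raise ValueError("coherence matrix must be symmetric")
    n = C.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = C[iu]
    n_edges = int(np.floor(edge_fraction * vals.size))
    if n_edges < 1:
        warnings.warn(
            "edge_fraction selects zero edges; taking the single strongest"
        )
        n_edges = 1
    order = np.argsort(vals)[::-1][:n_edges]
    nodes = np.union1d(iu[0][order], iu[1][order])
    return nodes
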