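"""fNIRS preprocessing: raw two-wavelength intensity -> clean ΔHbO/ΔHbR.

Chain (continuous-wave NIRS, 730/850 nm, 11 Hz):

1. intensity -> optical-density change, ``ΔOD = -log10(I / mean(I))``;
2. motion-artifact scrubbing: samples whose 0.5-s windowed peak-to-peak
   change exceeds ``sd_factor`` channel standard deviations are flagged and
   linearly interpolated (channels flagged beyond a fraction threshold are
   marked bad);
3. zero-phase Butterworth band-pass 0.01–0.1 Hz, removing drift and the
   cardiac (~1 Hz), respiratory (~0.3 Hz) and Mayer-wave (~0.1 Hz) bands;
4. modified Beer–Lambert law (MBLL): per channel, solve the 2x2 linear
   system ``ΔOD_λ = d · DPF(λ) · (ε_HbO(λ) ΔHbO + ε_HbR(λ) ΔHbR)`` for the
   chromophore concentration changes in μM;
5. per-channel temporal mean subtraction.

The chain is linear except for the artifact interpolation, so a common
intensity scaling per channel cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "OpticalRecording",
    "OdSeries",
    "HemoRecording",
    "MbllCoefficients",
    "PreprocessConfig",
    "DEFAULT_MBLL",
    "intensity_to_od",
    "scrub_motion_artifacts",
    "bandpass_filter",
    "od_to_hemoglobin",
    "preprocess_recording",
    "read_intensity_csv",
    "write_intensity_csv",
]


@dataclass(frozen=True)
class OpticalRecording:
    """Raw intensities, shape (n_channels, 2 wavelengths, n_times), a.u."""

    intensity: np.ndarray
    sampling_rate: float = 11.0
    wavelengths_nm: tuple[float, float] = (730.0, 850.0)
    source_detector_distance_cm: np.ndarray | float = 3.0

    def __post_init__(self):
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "intensity", inten)
        if inten.ndim != 3 or inten.shape[1] != 2:
            raise ValueError("intensity must have shape (channels, 2, times)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dist = np.broadcast_to(
            np.asarray(self.source_detector_distance_cm, dtype=float),
            (inten.shape[0],)).copy()
        if (dist <= 0).any():
            raise ValueError("source-detector distances must be positive")
        object.__setattr__(self, "source_detector_distance_cm", dist)

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_times(self) -> int:
        return self.intensity.shape[2]


@dataclass(frozen=True)
class OdSeries:
    """Optical-density change (base-10), shape (channels, 2, times)."""

    od: np.ndarray
    sampling_rate: float
    wavelengths_nm: tuple[float, float]
    source_detector_distance_cm: np.ndarray


@dataclass(frozen=True)
class HemoRecording:
    """Chromophore concentration changes in μM, shape (channels, times)."""

    hbo: np.ndarray
    hbr: np.ndarray
    sampling_rate: float
    artifact_mask: np.ndarray | None = None  # True where scrubbed
    bad_channels: frozenset = frozenset()


@dataclass(frozen=True)
class MbllCoefficients:
    """Extinction coefficients (1/(mM cm)) and DPF per wavelength.

    ``extinction[λ] = (ε_HbO, ε_HbR)``. Defaults are the standard tabulated
    molar extinction values for hemoglobin at 730/850 nm (base-10) and
    typical adult differential pathlength factors.
    """

    extinction: dict = field(default_factory=lambda: {
        730.0: (0.390, 1.1022),
        850.0: (1.058, 0.69132),
    })
    dpf: dict = field(default_factory=lambda: {730.0: 6.2, 850.0: 5.6})

    def system(self, wavelengths: tuple[float, float]) -> np.ndarray:
        """2x2 matrix M with rows DPF(λ)·(ε_HbO(λ), ε_HbR(λ))."""
        rows = []
        for wl in wavelengths:
            if wl not in self.extinction or wl not in self.dpf:
                raise KeyError(f"no MBLL coefficients for wavelength {wl} nm")
            e_hbo, e_hbr = self.extinction[wl]
            rows.append([self.dpf[wl] * e_hbo, self.dpf[wl] * e_hbr])
        m = np.asarray(rows, dtype=float)
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("singular extinction/DPF system")
        return m


DEFAULT_MBLL = MbllCoefficients()


def intensity_to_od(rec: OpticalRecording) -> OdSeries:
    """ΔOD(t) = -log10(I(t) / temporal mean), per channel and wavelength."""
    inten = rec.intensity
    if (inten <= 0).any():
        bad = np.unique(np.argwhere(inten <= 0)[:, 0])
        raise ValueError(f"non-positive intensity in channel(s) {bad.tolist()}")
    od = -np.log10(inten / inten.mean(axis=2, keepdims=True))
    return OdSeries(od=od, sampling_rate=rec.sampling_rate,
                    wavelengths_nm=rec.wavelengths_nm,
                    source_detector_distance_cm=rec.source_detector_distance_cm)


def _flag_windowed_p2p(x: np.ndarray, win: int,
                       threshold: np.ndarray) -> np.ndarray:
    """Flag every sample of any length-``win`` window whose peak-to-peak
    change exceeds ``threshold`` (thresholds broadcast over leading axes,
    filtering along the last axis)."""
    from scipy.ndimage import maximum_filter1d, minimum_filter1d
    p2p = (maximum_filter1d(x, win, axis=-1)
           - minimum_filter1d(x, win, axis=-1))
    hot = p2p > threshold
    # a sample belongs to every window covering it: dilate by the window
    return maximum_filter1d(hot.astype(np.uint8), win, axis=-1).astype(bool)


def _interpolate_flagged(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    clean = ~mask
    if clean.sum() == 0:
        return x
    idx = np.arange(x.size)
    out = x.copy()
    out[mask] = np.interp(idx[mask], idx[clean], x[clean])
    return out


def scrub_motion_artifacts(
    od: OdSeries,
    window_s: float = 0.5,
    sd_factor: float = 10.0,
    max_flag_fraction: float = 0.5,
) -> tuple[OdSeries, np.ndarray, frozenset]:
    """Flag and interpolate motion artifacts.

    A sample is flagged when, within any 0.5-s window containing it, the
    peak-to-peak OD change exceeds ``sd_factor`` times the channel's standard
    deviation (per wavelength). Flagged runs are linearly interpolated from
    the surrounding clean samples. Channels flagged on more than
    ``max_flag_fraction`` of samples are reported as bad.

    Returns ``(scrubbed, mask, bad_channels)`` with mask shaped
    (channels, times) — wavelengths are OR-combined, since motion moves both.
    """
    x = od.od
    n_ch, _, n_t = x.shape
    win = max(2, int(round(window_s * od.sampling_rate)))
    if win >= n_t:
        raise ValueError("scrub window must be shorter than the recording")
    sd = x.std(axis=2)  # (channels, wavelengths)
    thr = sd_factor * sd[:, :, None]
    thr[thr <= 0] = np.inf  # constant channels cannot be flagged
    mask = _flag_windowed_p2p(x, win, thr).any(axis=1)
    out = x.copy()
    bad = []
    for ch in range(n_ch):
        frac = mask[ch].mean()
        if frac >= max_flag_fraction:
            bad.append(ch)
        if mask[ch].any():
            for wl in range(2):
                out[ch, wl] = _interpolate_flagged(out[ch, wl], mask[ch])
    scrubbed = OdSeries(od=out, sampling_rate=od.sampling_rate,
                        wavelengths_nm=od.wavelengths_nm,
                        source_detector_distance_cm=od.source_detector_distance_cm)
    return scrubbed, mask, frozenset(bad)


def bandpass_filter(x: np.ndarray, sampling_rate: float,
                    low_hz: float = 0.01, high_hz: float = 0.1,
                    order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    nyq = sampling_rate / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz")
    b, a = signal.butter(order, (low_hz, high_hz), btype="band",
                         fs=sampling_rate)
    # two finite-window subtleties matter at a 0.01 Hz band edge: (1) a
    # linear drift, though nominally out of band, has windowed spectral
    # leakage throughout the passband and — because time is common to all
    # channels — produces spurious cross-channel correlation, so it is
    # removed exactly by linear detrending first; (2) the band edge's
    # impulse response spans ~1/low_hz s, comparable to the whole recording,
    # so pad-based filtfilt leaks large edge transients — Gustafsson's
    # method chooses initial conditions that minimize them instead
    x = signal.detrend(np.asarray(x, float), axis=-1, type="linear")
    # cap the transient fit at ~6 time constants of the slowest pole
    irlen = min(x.shape[-1] - 1, int(round(6 * sampling_rate / low_hz)))
    return signal.filtfilt(b, a, x, axis=-1, method="gust", irlen=irlen)


def od_to_hemoglobin(od: OdSeries,
                     coeffs: MbllCoefficients = DEFAULT_MBLL) -> HemoRecording:
    """Invert the MBLL 2x2 system per channel; concentrations in μM."""
    m = coeffs.system(od.wavelengths_nm)  # ΔOD = d * M @ ΔC[mM]
    minv = np.linalg.inv(m)
    d = od.source_detector_distance_cm[:, None, None]  # (ch,1,1)
    conc_mm = np.einsum("ij,cjt->cit", minv, od.od / d)
    conc_um = conc_mm * 1000.0
    return HemoRecording(hbo=conc_um[:, 0, :], hbr=conc_um[:, 1, :],
                         sampling_rate=od.sampling_rate)


def hemoglobin_to_od(hbo_um: np.ndarray, hbr_um: np.ndarray,
                     distance_cm: np.ndarray | float,
                     wavelengths_nm: tuple[float, float] = (730.0, 850.0),
                     coeffs: MbllCoefficients = DEFAULT_MBLL) -> np.ndarray:
    """Forward MBLL: (channels, times) μM concentrations -> (channels, 2, times) ΔOD.

    The exact inverse of :func:`od_to_hemoglobin`; used by the synthetic
    generator so the full chain can be exercised end-to-end.
    """
    m = coeffs.system(wavelengths_nm)
    conc_mm = np.stack([hbo_um, hbr_um], axis=1) / 1000.0  # (ch, 2, t)
    d = np.broadcast_to(np.asarray(distance_cm, float),
                        (hbo_um.shape[0],))[:, None, None]
    return d * np.einsum("ij,cjt->cit", m, conc_mm)


@dataclass(frozen=True)
class PreprocessConfig:
    scrub_window_s: float = 0.5
    scrub_sd_factor: float = 10.0
    scrub_max_flag_fraction: float = 0.5
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.1
    bandpass_order: int = 3
    mbll: MbllCoefficients = field(default_factory=MbllCoefficients)


def preprocess_recording(rec: OpticalRecording,
                         config: PreprocessConfig = PreprocessConfig()
                         ) -> HemoRecording:
    """Full deterministic chain: OD -> scrub -> band-pass -> MBLL -> demean."""
    od = intensity_to_od(rec)
    od, mask, bad = scrub_motion_artifacts(
        od, window_s=config.scrub_window_s, sd_factor=config.scrub_sd_factor,
        max_flag_fraction=config.scrub_max_flag_fraction)
    filtered = bandpass_filter(od.od, od.sampling_rate,
                               low_hz=config.bandpass_low_hz,
                               high_hz=config.bandpass_high_hz,
                               order=config.bandpass_order)
    od = OdSeries(od=filtered, sampling_rate=od.sampling_rate,
                  wavelengths_nm=od.wavelengths_nm,
                  source_detector_distance_cm=od.source_detector_distance_cm)
    hemo = od_to_hemoglobin(od, config.mbll)
    hbo = hemo.hbo - hemo.hbo.mean(axis=1, keepdims=True)
    hbr = hemo.hbr - hemo.hbr.mean(axis=1, keepdims=True)
    return HemoRecording(hbo=hbo, hbr=hbr, sampling_rate=hemo.sampling_rate,
                         artifact_mask=mask, bad_channels=bad)


# ---------------------------------------------------------------------------
# I/O: long CSV (time_s, channel, wavelength_nm, intensity)


def write_intensity_csv(rec: OpticalRecording, path) -> None:
    n_ch, _, n_t = rec.intensity.shape
    t = np.arange(n_t) / rec.sampling_rate
    frames = []
    for wl_idx, wl in enumerate(rec.wavelengths_nm):
        df = pd.DataFrame({
            "time_s": np.tile(t, n_ch),
            "channel": np.repeat(np.arange(1, n_ch + 1), n_t),
            "wavelength_nm": wl,
            "intensity": rec.intensity[:, wl_idx, :].ravel(),
        })
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False)


def read_intensity_csv(path, source_detector_distance_cm=3.0) -> OpticalRecording:
    df = pd.read_csv(path)
    wls = sorted(df["wavelength_nm"].unique())
    if len(wls) != 2:
        raise ValueError("expected exactly two wavelengths")
    channels = sorted(df["channel"].unique())
    times = np.sort(df["time_s"].unique())
    fs = float(1.0 / np.median(np.diff(times)))
    inten = np.empty((len(channels), 2, times.size))
    for wi, wl in enumerate(wls):
        sub = df[df["wavelength_nm"] == wl].pivot(
            index="channel", columns="time_s", values="intensity")
        inten[:, wi, :] = sub.loc[channels, times].to_numpy()
    return OpticalRecording(intensity=inten, sampling_rate=fs,
                            wavelengths_nm=(float(wls[0]), float(wls[1])),
                            source_detector_distance_cm=source_detector_distance_cm)
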