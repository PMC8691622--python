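"""Laminar depth alignment and per-band depth profiles.

Linear-array penetrations differ in cortical thickness and probe angle, so
channels are aligned on a relative depth (ReD) scale in [0, 1]:

* the channel with the lowest SF selectivity marks the middle of the input
  layer (Cha1, ReD 0.5);
* the cortical surface sits 0.050 mm above the uppermost channel with
  visually driven spiking (Cha2; MUA SNR > 3 and the 3 consecutive deeper
  channels also > 3), ReD 0;
* the gray/white-matter boundary sits 0.050 mm below the deepest such
  channel (Cha3; SNR > 3 with the 3 consecutive shallower channels > 3),
  ReD 1.

ReD is piecewise linear in physical depth on the two segments
surface -> Cha1 and Cha1 -> white matter.  ReD 0.375–0.625 is the input
layer.  Band-power peak positions across sessions are compared with a
session-resampling bootstrap (one-sided: p = proportion of resamples in
which the first band's mean peak ReD exceeds the second's).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np

from .model import COMPONENT_LABELS, DEFAULT_SNR_THRESHOLD

ANCHOR_OFFSET_MM = 0.050
INPUT_LAYER = (0.375, 0.625)


class Anchors(NamedTuple):
    cha1: int  # lowest SF selectivity -> ReD 0.5
    cha2: int  # uppermost driven channel -> surface reference above it
    cha3: int  # deepest driven channel -> white-matter reference below it


@dataclass
class LaminarProfile:
    session_id: str
    depths_mm: np.ndarray
    red: np.ndarray
    band_power: np.ndarray  # (3, n_channels) in LG/MG/HG order
    anchors: Anchors
    clipped: np.ndarray | None = None  # channels outside [surface, wm]

    def in_input_layer(self) -> np.ndarray:
        return (self.red >= INPUT_LAYER[0]) & (self.red <= INPUT_LAYER[1])


def find_anchors(
    mua_snr: Sequence[float],
    sf_selectivity: Sequence[float],
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    run_length: int = 3,
) -> Anchors:
    """Locate the three alignment channels (channel 0 = shallowest).

    Cha2 is the uppermost channel whose SNR exceeds the threshold together
    with the ``run_length`` consecutive channels below it; Cha3 is the
    symmetric deepest channel.  Cha1 is the channel with the lowest SF
    selectivity (shallowest on ties) and must lie within [Cha2, Cha3],
    otherwise the session is rejected.
    """
    snr = np.asarray(mua_snr, dtype=float)
    sel = np.asarray(sf_selectivity, dtype=float)
    n = snr.size
    if n < 8:
        raise ValueError("need at least 8 channels")
    if sel.size != n:
        raise ValueError("mua_snr and sf_selectivity length mismatch")
    driven = snr > snr_threshold

    cha2 = None
    for i in range(n - run_length):
        if driven[i] and np.all(driven[i + 1 : i + 1 + run_length]):
            cha2 = i
            break
    cha3 = None
    for i in range(n - 1, run_length - 1, -1):
        if driven[i] and np.all(driven[i - run_length : i]):
            cha3 = i
            break
    if cha2 is None or cha3 is None:
        raise ValueError("no channel satisfies the consecutive-SNR run condition")
    cha1 = int(np.argmin(sel))  # argmin returns the shallowest tied channel
    if not (cha2 <= cha1 <= cha3):
        raise ValueError(
            f"session rejected: Cha1 ({cha1}) outside the [Cha2, Cha3] span "
            f"[{cha2}, {cha3}]"
        )
    return Anchors(cha1=cha1, cha2=cha2, cha3=cha3)


def assign_red(
    channel_depths: Sequence[float],
    anchors: Anchors,
    offset_mm: float = ANCHOR_OFFSET_MM,
):
    """Piecewise-linear ReD for each channel.

    The surface reference (``offset_mm`` above Cha2) maps to 0, Cha1's depth
    to 0.5, and the white-matter reference (``offset_mm`` below Cha3) to 1.
    Channels outside [surface, white matter] are clipped and flagged.

    Returns ``(red, clipped)`` arrays.
    """
    depths = np.asarray(channel_depths, dtype=float)
    if np.any(np.diff(depths) <= 0):
        raise ValueError("channel depths must be strictly increasing")
    surface = depths[anchors.cha2] - offset_mm
    wm = depths[anchors.cha3] + offset_mm
    mid = depths[anchors.cha1]
    if not surface < mid < wm:
        raise ValueError("non-monotone anchor depths")
    red = np.where(
        depths <= mid,
        0.5 * (depths - surface) / (mid - surface),
        0.5 + 0.5 * (depths - mid) / (wm - mid),
    )
    clipped = (red < 0) | (red > 1)
    return np.clip(red, 0.0, 1.0), clipped


def band_power_profile(
    session,
    band_windows=None,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    mode: str = "stored",
    window=(0.3, 2.0),
) -> LaminarProfile:
    """Attach per-channel LG/MG/HG power to ReD coordinates.

    ``session`` is a :class:`~gammasf.synthetic.LaminarSession` (or any
    object with ``depths_mm``, ``mua_snr``, ``sf_selectivity`` and either
    stored ``band_power`` or per-channel ``recordings``).  ``mode``:
    ``"stored"`` uses the stored band powers; ``"spectra"`` recomputes raw
    band power from each channel's recording at that band's best SF.
    """
    from .model import DEFAULT_BAND_WINDOWS
    from .spectral import spectrum_grid

    band_windows = dict(band_windows or DEFAULT_BAND_WINDOWS)
    anchors = find_anchors(session.mua_snr, session.sf_selectivity, snr_threshold)
    red, clipped = assign_red(session.depths_mm, anchors)

    if mode == "stored" and getattr(session, "band_power", None) is not None:
        power = np.asarray(session.band_power, dtype=float)
    elif session.recordings is not None:
        n_ch = len(session.recordings)
        power = np.zeros((3, n_ch))
        for ch, rec in enumerate(session.recordings):
            grid = spectrum_grid(rec, window=window)
            for bi, lab in enumerate(COMPONENT_LABELS):
                lo, hi = band_windows[lab]
                in_band = (grid.frequencies >= lo) & (grid.frequencies <= hi)
                band = grid.power[:, in_band].mean(axis=1)
                if grid.blank_power is not None:
                    band = band - grid.blank_power[in_band].mean()
                power[bi, ch] = band.max()  # at the band's best SF
        power = np.maximum(power, 0.0)
    else:
        raise ValueError("session carries neither band powers nor recordings")
    if power.shape[1] != red.size:
        raise ValueError("missing channels: band power does not cover all depths")
    return LaminarProfile(
        session_id=getattr(session, "session_id", ""),
        depths_mm=np.asarray(session.depths_mm, dtype=float),
        red=red, band_power=power, anchors=anchors, clipped=clipped,
    )


class PeakRed(NamedTuple):
    red: float
    boundary: bool  # peak sits at the first/last channel


def peak_red(profile: LaminarProfile, band: str) -> PeakRed:
    """ReD of the channel with maximum power in ``band`` (shallower wins
    ties; boundary peaks are flagged)."""
    bi = COMPONENT_LABELS.index(band)
    p = profile.band_power[bi]
    if p.size < 8:
        raise ValueError("need at least 8 channels")
    if np.ptp(p) == 0:
        raise ValueError("all-equal band powers: peak undefined")
    i = int(np.argmax(p))  # argmax -> shallowest tied channel
    return PeakRed(float(profile.red[i]), boundary=i in (0, p.size - 1))


def bootstrap_peak_locations(
    session_peaks,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """Session-resampling bootstrap comparison of per-band peak ReDs.

    ``session_peaks`` is (n_sessions, 3) in LG/MG/HG order.  Each draw
    resamples sessions with replacement (resample size = n_sessions) and
    records the mean peak ReD per band; for each ordered band pair the
    p-value is the proportion of draws in which the first band's mean is
    strictly larger than the second's (null: it is no larger).  With exact
    ties across all draws this strict rule yields p = 0.
    """
    peaks = np.asarray(session_peaks, dtype=float)
    if peaks.ndim != 2 or peaks.shape[1] != 3:
        raise ValueError("session_peaks must be (n_sessions, 3)")
    n_sessions = peaks.shape[0]
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_sessions, size=(n_boot, n_sessions))
    means = peaks[idx].mean(axis=1)  # (n_boot, 3)
    out = {}
    for a, b in combinations(range(3), 2):
        la, lb = COMPONENT_LABELS[a], COMPONENT_LABELS[b]
        out[(la, lb)] = float(np.mean(means[:, a] > means[:, b]))
        out[(lb, la)] = float(np.mean(means[:, b] > means[:, a]))
    return out
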