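"""Receptor-noise-limited (RNL) chromatic discriminability.

Computes the chromatic contrast dS (in just-noticeable-difference
units) between two stimuli for a receiver whose colour discrimination
is limited by independent receptor noise.  Receiver channel noise is
set from a Weber fraction anchored to the most abundant receptor class
(``e_i = w * sqrt(eta_max / eta_i)``), receptor signals are the natural
logs of quantum-catch ratios, and dS is evaluated with the general
n-channel quadratic form, which reduces exactly to the published
dichromat/trichromat/tetrachromat closed forms.  A contrast below
1 JND is conventionally indistinguishable.  Only the chromatic channel
is modelled; achromatic (luminance) contrast dL is deliberately not
implemented.

Built-in receivers: trichromatic ``human`` (sw:mw:lw cone ratios
0.057:0.314:0.629), tetrachromatic ``bluetit`` (uv:sw:mw:lw ratios
1:1.92:2.68:2.7) and trichromatic ``moth`` (uv:sw:mw ratios 1:1:1),
all with Weber fraction 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .specimen import CHANNELS, MultichannelSpecimen
from .features import roi_colour_means

__all__ = [
    "ReceiverModel",
    "QuantumCatchVector",
    "builtin_receiver",
    "receptor_noise",
    "quantum_catches",
    "chromatic_contrast",
    "closed_form_contrast",
    "roi_means_table",
    "pairwise_contrast_table",
    "discriminability_summary",
    "CATCH_FLOOR",
]

#: Quantum catches are floored here so log ratios stay finite.
CATCH_FLOOR = 1e-6


@dataclass(frozen=True)
class ReceiverModel:
    """A receiver: ordered receptor channels, cone ratios, Weber fraction.

    ``mapping`` optionally gives a linear map from the four camera
    channels (uv, sw, mw, lw) to the receiver's channels as an
    ``(n_receptors, 4)`` matrix; by default the receiver's channels are
    selected from the like-named camera channels.
    """

    name: str
    channels: tuple[str, ...]
    ratios: tuple[float, ...]
    weber: float = 0.05
    mapping: tuple | None = None

    def __post_init__(self) -> None:
        if len(self.channels) < 2:
            raise ValueError("a receiver needs at least two channels")
        if len(self.ratios) != len(self.channels):
            raise ValueError("one cone ratio per channel required")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("cone ratios must be positive")
        if self.weber <= 0:
            raise ValueError("Weber fraction must be positive")
        if self.mapping is not None:
            M = np.asarray(self.mapping, dtype=float)
            if M.shape != (len(self.channels), len(CHANNELS)):
                raise ValueError(
                    f"mapping must be ({len(self.channels)}, {len(CHANNELS)})"
                )

    @property
    def n(self) -> int:
        return len(self.channels)


_BUILTINS = {
    "human": ReceiverModel("human", ("sw", "mw", "lw"), (0.057, 0.314, 0.629)),
    "bluetit": ReceiverModel("bluetit", ("uv", "sw", "mw", "lw"), (1.0, 1.92, 2.68, 2.7)),
    "moth": ReceiverModel("moth", ("uv", "sw", "mw"), (1.0, 1.0, 1.0)),
}
_BUILTINS["avian"] = _BUILTINS["bluetit"]


def builtin_receiver(name: str) -> ReceiverModel:
    """Fetch a built-in receiver model by name (human, bluetit/avian, moth)."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise ValueError(f"unknown receiver {name!r}; built-ins: {sorted(_BUILTINS)}") from None


@dataclass
class QuantumCatchVector:
    """Per-receptor quantum catches (strictly positive after flooring)."""

    channels: tuple[str, ...]
    values: np.ndarray
    floored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("quantum catches must be strictly positive")


def receptor_noise(rx: ReceiverModel) -> np.ndarray:
    """Noise standard deviation per receptor channel.

    ``e_i = w * sqrt(eta_max / eta_i)`` with ``w`` the Weber fraction of
    the most abundant class (relative abundance ``eta_max``): the most
    abundant channel gets exactly ``w``, rarer channels are noisier.
    """
    eta = np.asarray(rx.ratios, dtype=float)
    return rx.weber * np.sqrt(eta.max() / eta)


def quantum_catches(roi_means: dict[str, float], rx: ReceiverModel) -> QuantumCatchVector:
    """Quantum catches of a receiver viewing a stimulus with given camera-channel means.

    Default is identity selection of the receiver's channels from the
    like-named camera channels; a receiver ``mapping`` matrix applies a
    full linear camera-to-receptor transform instead.  Non-positive
    catches are floored at ``CATCH_FLOOR`` and flagged.
    """
    if rx.mapping is not None:
        cam = np.array([float(roi_means[c]) for c in CHANNELS])
        vals = np.asarray(rx.mapping, dtype=float) @ cam
    else:
        missing = [c for c in rx.channels if c not in roi_means]
        if missing:
            raise ValueError(f"receiver {rx.name} needs camera channels {missing}")
        vals = np.array([float(roi_means[c]) for c in rx.channels])
    floored = bool(np.any(vals < CATCH_FLOOR))
    vals = np.maximum(vals, CATCH_FLOOR)
    return QuantumCatchVector(rx.channels, vals, floored)


def _delta_f(qA: QuantumCatchVector, qB: QuantumCatchVector) -> np.ndarray:
    if qA.channels != qB.channels:
        raise ValueError("quantum catch vectors have mismatching channel sets")
    return np.log(qA.values / qB.values)


def chromatic_contrast(qA: QuantumCatchVector, qB: QuantumCatchVector,
                       rx: ReceiverModel) -> float:
    """Chromatic contrast dS between two stimuli, in JND units.

    Receptor signals are ``delta f_i = ln(qA_i / qB_i)`` and dS is the
    general n-channel RNL quadratic form

        dS^2 = df' (V^-1 - V^-1 1 1' V^-1 / (1' V^-1 1)) df,   V = diag(e_i^2),

    i.e. the noise-weighted distance after projecting out the achromatic
    (equal-increment) direction.  This equals the published dichromat,
    trichromat and tetrachromat closed forms.
    """
    df = _delta_f(qA, qB)
    if len(df) != rx.n:
        raise ValueError("catch vectors do not match the receiver's channel count")
    e = receptor_noise(rx)
    vinv = 1.0 / e**2
    proj = df - np.dot(vinv, df) / vinv.sum()
    ds2 = float(np.dot(df * vinv, proj))
    return float(np.sqrt(max(ds2, 0.0)))


def closed_form_contrast(delta_f: np.ndarray, e: np.ndarray) -> float:
    """Published pairwise closed forms for 2-4 receptor channels.

    Reference implementation used to validate the matrix form:
    numerator terms sum ``(prod of noises outside the pair)^2 *
    (df_i - df_j)^2`` over channel pairs; denominator sums ``(prod of
    noises excluding one channel)^2`` over channels.
    """
    delta_f = np.asarray(delta_f, dtype=float)
    e = np.asarray(e, dtype=float)
    n = len(e)
    if n < 2 or n > 4:
        raise ValueError("closed forms cover 2 to 4 channels")
    idx = range(n)
    num = 0.0
    for i, j in combinations(idx, 2):
        others = np.prod([e[k] for k in idx if k not in (i, j)]) if n > 2 else 1.0
        num += (others**2) * (delta_f[i] - delta_f[j]) ** 2
    den = sum(np.prod([e[k] for k in idx if k != i]) ** 2 for i in idx)
    return float(np.sqrt(num / den))


# ---------------------------------------------------------------------------
# cohort-level tables
# ---------------------------------------------------------------------------

def roi_means_table(cohort: list[MultichannelSpecimen],
                    rois: tuple[str, ...] = ("AB", "FW", "HW")) -> pd.DataFrame:
    """Long-form per-specimen, per-ROI camera-channel means."""
    rows = []
    for spec in cohort:
        for roi in rois:
            means, _ = roi_colour_means(spec, roi)
            rows.append(dict(id=spec.id, genotype=spec.meta.get("genotype"),
                             roi=roi, **means))
    return pd.DataFrame(rows)


def pairwise_contrast_table(roi_means: pd.DataFrame,
                            receivers: list[ReceiverModel] | None = None,
                            threshold: float = 1.0) -> pd.DataFrame:
    """All unordered specimen-pair chromatic contrasts per ROI and receiver.

    ``roi_means`` is the output of :func:`roi_means_table`.  Each record
    carries the genotype-pair label (e.g. ``WW-Wy``) for summarising,
    the contrast dS and the ``discriminable`` flag (dS > ``threshold``).
    Within-genotype pairs are included, labelled e.g. ``WW-WW``.
    """
    if receivers is None:
        receivers = [builtin_receiver(n) for n in ("human", "bluetit", "moth")]
    rows = []
    for roi, grp in roi_means.groupby("roi", sort=False):
        recs = grp.to_dict("records")
        for rx in receivers:
            catches = [quantum_catches({c: r[c] for c in CHANNELS}, rx) for r in recs]
            for i, j in combinations(range(len(recs)), 2):
                ds = chromatic_contrast(catches[i], catches[j], rx)
                pair = "-".join(sorted([str(recs[i]["genotype"]), str(recs[j]["genotype"])]))
                rows.append(dict(id_a=recs[i]["id"], id_b=recs[j]["id"],
                                 genotype_pair=pair, roi=roi, receiver=rx.name,
                                 dS=ds, discriminable=ds > threshold))
    return pd.DataFrame(rows)


def discriminability_summary(table: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Median dS and fraction of pairs above threshold per (pair, ROI, receiver)."""
    if len(table) == 0:
        raise ValueError("empty contrast table")
    out = (
        table.groupby(["genotype_pair", "roi", "receiver"])
        .agg(median_dS=("dS", "median"),
             frac_discriminable=("dS", lambda s: float((s > threshold).mean())),
             n_pairs=("dS", "size"))
        .reset_index()
    )
    return out
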