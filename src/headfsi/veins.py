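"""Bridging veins and acute subdural haematoma (ASDH) risk.

The eleven pairs of parasagittal bridging veins connect the cerebral cortex
to the superior sagittal sinus and are modelled as geometric springs: an
attachment riding the brain surface, an attachment riding the skull/sinus,
and an engineering strain computed from the end-to-end distance change.
Rupture risk is assessed against the cadaveric ultimate-strain data of
isolated human bridging veins: ultimate strain 0.5 +/- 0.16, lowest observed
rupture strain 0.36. A peak strain at or above the lowest observed rupture
strain flags a possible ASDH.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BridgingVein",
    "RuptureThresholds",
    "RuptureAssessment",
    "bv_catalog",
    "bv_strain",
    "strain_from_tangential",
    "assess_rupture",
]


@dataclass(frozen=True)
class BridgingVein:
    """A parasagittal bridging vein as a spring element.

    ``rest_length`` in mm; ``angle`` in degrees counterclockwise from the
    mid-sagittal line to the vein axis.
    """

    name: str
    rest_length: float
    angle: float

    def __post_init__(self) -> None:
        if self.rest_length <= 0:
            raise ValueError("rest_length must be positive")
        if not 0.0 <= self.angle < 180.0:
            raise ValueError("angle must lie in [0, 180)")

    @property
    def axis(self) -> np.ndarray:
        """Unit rest-axis vector in the (mid-sagittal, transverse) plane."""
        th = np.deg2rad(self.angle)
        return np.array([np.cos(th), np.sin(th)])


# measured lengths (mm) and angles (deg, counterclockwise from mid-sagittal)
# of the 11 modelled parasagittal bridging-vein pairs
_CATALOG = (
    ("Frontopolar", 16.5, 87.0),
    ("Anterior frontal", 15.8, 103.0),
    ("Middle frontal", 9.7, 69.0),
    ("Posterior frontal", 13.7, 64.0),
    ("Vein of Trolard", 18.4, 47.0),
    ("Precentral", 18.2, 46.0),
    ("Central", 14.9, 61.0),
    ("Post-central", 15.0, 59.0),
    ("Anterior parietal", 8.8, 44.0),
    ("Posterior parietal", 19.9, 66.0),
    ("Occipital", 17.8, 74.0),
)


def bv_catalog() -> list[BridgingVein]:
    """The 11 named parasagittal bridging veins with measured geometry."""
    return [BridgingVein(n, l, a) for n, l, a in _CATALOG]


def bv_strain(vein: BridgingVein, cortical_disp, sinus_disp) -> float:
    """Engineering strain of a vein under end displacements [mm].

    ``cortical_disp`` and ``sinus_disp`` are planar displacement vectors of
    the two attachments in the vein's (mid-sagittal, transverse) frame, mm.
    Strain is ``(deformed length - rest length) / rest length`` floored at
    zero: a slack vein buckles rather than supports compression, and rupture
    risk concerns tension only.
    """
    c = np.asarray(cortical_disp, float)
    s = np.asarray(sinus_disp, float)
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(s))):
        raise ValueError("displacements must be finite")
    rest_vec = vein.rest_length * vein.axis
    new_len = float(np.linalg.norm(rest_vec + (s - c)))
    return max(0.0, (new_len - vein.rest_length) / vein.rest_length)


def strain_from_tangential(vein: BridgingVein, relative_disp_mm: float) -> float:
    """Strain under a pure tangential brain-skull relative displacement.

    In the shear-gap surrogate the relative motion is a single scalar along
    the impact's tangential direction (taken along the mid-sagittal line).
    The vein sees it decomposed onto its own axis: an axial component
    ``d*cos(angle)`` and a transverse component ``d*sin(angle)``.
    """
    d = abs(float(relative_disp_mm))
    return bv_strain(vein, (0.0, 0.0), (d, 0.0))


@dataclass(frozen=True)
class RuptureThresholds:
    """Cadaveric bridging-vein ultimate-strain statistics."""

    ultimate_mean: float = 0.5
    ultimate_sd: float = 0.16
    lowest_observed: float = 0.36

    def __post_init__(self) -> None:
        if self.ultimate_sd < 0:
            raise ValueError("ultimate_sd must be non-negative")
        if self.lowest_observed > self.ultimate_mean:
            raise ValueError("lowest_observed cannot exceed ultimate_mean")

    @property
    def ultimate_range(self) -> tuple[float, float]:
        """mean +/- one standard deviation."""
        return (self.ultimate_mean - self.ultimate_sd,
                self.ultimate_mean + self.ultimate_sd)


@dataclass
class RuptureAssessment:
    """Per-vein peak strains, categories and the ASDH flag list."""

    peak_strains: dict[str, float]
    categories: dict[str, str]
    flagged_veins: list[str]
    thresholds: RuptureThresholds = field(default_factory=RuptureThresholds)

    @property
    def max_strain(self) -> float:
        return max(self.peak_strains.values()) if self.peak_strains else 0.0

    @property
    def any_flagged(self) -> bool:
        return len(self.flagged_veins) > 0

    def to_dict(self) -> dict:
        return {
            "veins": [
                {
                    "vein": name,
                    "peak_strain": self.peak_strains[name],
                    "category": self.categories[name],
                    "flagged": name in self.flagged_veins,
                }
                for name in self.peak_strains
            ],
            "max_strain": self.max_strain,
            "possible_asdh": self.any_flagged,
            "thresholds": {
                "ultimate_mean": self.thresholds.ultimate_mean,
                "ultimate_sd": self.thresholds.ultimate_sd,
                "lowest_observed": self.thresholds.lowest_observed,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def assess_rupture(
    peaks: dict[str, float], thresholds: RuptureThresholds | None = None
) -> RuptureAssessment:
    """Classify per-vein peak strains against the rupture thresholds.

    A vein is ``below_lowest_rupture`` when its peak falls short of the
    lowest observed rupture strain, ``within_ultimate_range`` up to one
    standard deviation above the ultimate mean, and ``above_ultimate_range``
    beyond that. Flagged (possible ASDH) veins are those at or above the
    lowest observed rupture strain — the operative comparison for declaring
    rupture plausible.
    """
    th = thresholds or RuptureThresholds()
    hi = th.ultimate_range[1]
    categories: dict[str, str] = {}
    flagged: list[str] = []
    for name, peak in peaks.items():
        peak = float(peak)
        if peak < 0:
            raise ValueError(f"negative peak strain for {name}")
        if peak < th.lowest_observed:
            categories[name] = "below_lowest_rupture"
        elif peak <= hi:
            categories[name] = "within_ultimate_range"
        else:
            categories[name] = "above_ultimate_range"
        if peak >= th.lowest_observed:
            flagged.append(name)
    return RuptureAssessment(dict(peaks), categories, flagged, th)
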