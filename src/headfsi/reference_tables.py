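"""Published CORA validation ratings for the KTH head model.

Per-case component scores (V, G, P, C1, B) reported for the two brain-skull
interface treatments of the KTH finite element head model: the original
Lagrangian "sliding" CSF contact and the ALE fluid-structure-interaction
(FSI) CSF. The relative-displacement table covers three cadaver impact
reconstructions (sagittal C288T3, coronal C380T4, horizontal C380T5); the
pressure table covers three intracranial pressure-measurement sites of a
frontal-impact reconstruction.

These rows are *inputs* to the aggregation operations (cross-case averaging,
percent improvement, classification); the package recomputes every summary
from them rather than storing summary values.
"""

from __future__ import annotations

from .cora import RatingComponents

__all__ = [
    "RELATIVE_DISPLACEMENT_RATINGS",
    "PRESSURE_RATINGS",
]


def _rc(v, g, p, c1, b) -> RatingComponents:
    return RatingComponents(V=v, G=g, P=p, C1=c1, B=b)


#: brain-skull relative displacement validation, per impact case and mode
RELATIVE_DISPLACEMENT_RATINGS: dict[str, dict[str, RatingComponents]] = {
    "C288T3": {
        "fsi": _rc(6.43, 3.75, 7.60, 3.27, 5.30),
        "sliding": _rc(5.97, 1.95, 7.22, 2.48, 4.40),
    },
    "C380T4": {
        "fsi": _rc(7.24, 4.99, 6.51, 3.65, 5.60),
        "sliding": _rc(6.02, 4.10, 5.63, 2.82, 4.65),
    },
    "C380T5": {
        "fsi": _rc(7.85, 4.01, 9.50, 4.59, 6.27),
        "sliding": _rc(7.67, 3.97, 7.07, 4.04, 5.69),
    },
}

#: intracranial pressure validation, per measurement site and mode
PRESSURE_RATINGS: dict[str, dict[str, RatingComponents]] = {
    "Frontal": {
        "fsi": _rc(9.92, 7.75, 9.99, 9.99, 9.41),
        "sliding": _rc(9.99, 9.52, 9.99, 9.99, 9.87),
    },
    "Parietal": {
        "fsi": _rc(9.92, 9.44, 9.99, 9.99, 9.83),
        "sliding": _rc(9.99, 8.90, 9.99, 9.99, 9.71),
    },
    "Fossa": {
        "fsi": _rc(8.96, 9.32, 9.99, 7.69, 9.06),
        "sliding": _rc(9.99, 8.64, 9.99, 7.67, 9.07),
    },
}
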