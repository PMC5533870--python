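"""Named chemical-shift windows for the urinary discriminant metabolites.

The eight regions below are the variable-size integration windows of the
metabolites that separate prostate-cancer (PCa) urine from benign prostatic
hyperplasia (BPH) urine in 500 MHz CPMG spectra.  Windows are stored as
(low, high) ppm with low < high; display order follows the ppm axis.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MetaboliteRegion:
    """A named ppm window used for variable-size bucket integration."""

    name: str
    window: tuple[float, float]

    def __post_init__(self) -> None:
        low, high = self.window
        if not low < high:
            raise ValueError(f"region {self.name!r}: window low must be < high")

    @property
    def low(self) -> float:
        return self.window[0]

    @property
    def high(self) -> float:
        return self.window[1]


#: Integration windows (ppm) of the discriminant urinary metabolites.
#: U1 is an unassigned resonance carried as an anonymous region.
DISCRIMINANT_WINDOWS: dict[str, tuple[float, float]] = {
    "BCAA": (0.842, 0.930),
    "glutamate": (2.081, 2.115),
    "dimethylglycine": (2.922, 2.944),
    "glycine": (3.567, 3.582),
    "pseudouridine": (4.277, 4.309),
    "U1": (6.478, 6.496),
    "fumarate": (6.498, 6.551),
    "4-imidazole-acetate": (8.517, 8.567),
}

#: Reported group-mean integrated intensities (arbitrary units) in the BPH
#: reference group; used as base concentrations by the cohort simulator.
BPH_MEAN_INTENSITY: dict[str, float] = {
    "BCAA": 13.10,
    "glutamate": 11.72,
    "dimethylglycine": 20.56,
    "glycine": 23.29,
    "pseudouridine": 6.88,
    "U1": 0.69,
    "fumarate": 0.99,
    "4-imidazole-acetate": 1.77,
}

#: Reported group-mean integrated intensities in the PCa group.
PCA_MEAN_INTENSITY: dict[str, float] = {
    "BCAA": 14.33,
    "glutamate": 12.42,
    "dimethylglycine": 17.17,
    "glycine": 20.49,
    "pseudouridine": 7.68,
    "U1": 0.45,
    "fumarate": 0.87,
    "4-imidazole-acetate": 1.37,
}

#: PCa-vs-BPH fold changes implied by the reported group means; these are the
#: cohort simulator's default effect map (group B relative to group A).
PCA_VS_BPH_FOLD_CHANGE: dict[str, float] = {
    name: PCA_MEAN_INTENSITY[name] / BPH_MEAN_INTENSITY[name]
    for name in DISCRIMINANT_WINDOWS
}


def discriminant_regions() -> list[MetaboliteRegion]:
    """The eight discriminant windows as :class:`MetaboliteRegion` objects."""
    return [MetaboliteRegion(n, w) for n, w in DISCRIMINANT_WINDOWS.items()]
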