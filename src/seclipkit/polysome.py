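"""Polysome-gradient quantification: Simpson's-rule areas and P/M ratios.

An absorbance trace is a uniformly sampled A254-style signal along the
sucrose gradient with named fraction regions (at minimum the 80S monosome
peak and the polysome span). Region areas are computed by composite
Simpson's rule on the baseline-subtracted signal; the polysome:monosome
ratio of those areas summarizes global translational activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.integrate import simpson, trapezoid

logger = logging.getLogger(__name__)


@dataclass
class AbsorbanceTrace:
    """Uniformly sampled gradient absorbance with named fraction regions.

    Regions are half-open position ranges in gradient units; boundaries are
    snapped to the nearest sample point at integration time.
    """

    positions: np.ndarray
    absorbance: np.ndarray
    regions: Mapping[str, tuple[float, float]]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.absorbance.shape:
            raise ValueError("positions and absorbance must be equal-length 1-D arrays")
        d = np.diff(self.positions)
        if np.any(d <= 0):
            raise ValueError("positions must be strictly increasing")
        if d.size and not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
            raise ValueError("positions must be uniformly spaced")
        lo, hi = self.positions[0], self.positions[-1]
        for name, (a, b) in self.regions.items():
            if not (lo <= a < b <= hi):
                raise ValueError(f"region {name!r} [{a}, {b}) outside trace span [{lo}, {hi}]")
        m, p = self.regions.get("monosome_80S"), self.regions.get("polysome")
        if m and p and not (m[1] <= p[0] or p[1] <= m[0]):
            raise ValueError("monosome_80S and polysome regions must be disjoint")

    @classmethod
    def from_table(
        cls,
        path: str,
        regions: Mapping[str, tuple[float, float]],
        baseline: float = 0.0,
        sep: Optional[str] = None,
    ) -> "AbsorbanceTrace":
        """Load a two-column (position, absorbance) TSV/CSV trace."""
        import pandas as pd

        df = pd.read_csv(path, sep=sep, engine="python")
        return cls(
            positions=df.iloc[:, 0].to_numpy(float),
            absorbance=df.iloc[:, 1].to_numpy(float),
            regions=dict(regions),
            baseline=baseline,
        )

    def region_slice(self, region: str) -> slice:
        if region not in self.regions:
            raise KeyError(f"unknown region {region!r}; have {sorted(self.regions)}")
        a, b = self.regions[region]
        i = int(np.argmin(np.abs(self.positions - a)))
        j = int(np.argmin(np.abs(self.positions - b)))
        if self.positions[i] != a or self.positions[j] != b:
            logger.info(
                "region %r snapped to samples [%g, %g]",
                region,
                self.positions[i],
                self.positions[j],
            )
        return slice(i, j + 1)

    def set_baseline_from_region(self, blank_region: str) -> None:
        """Constant baseline = minimum absorbance within a named blank region."""
        sl = self.region_slice(blank_region)
        self.baseline = float(np.min(self.absorbance[sl]))


def simpson_auc(trace: AbsorbanceTrace, region: str) -> float:
    """Composite Simpson's-rule area of the baseline-subtracted absorbance
    over a named region.

    With an odd number of intervals, the final interval is integrated by the
    trapezoid rule and added to the Simpson area over the preceding even
    count. Post-baseline negative values are clipped at 0.
    """
    sl = trace.region_slice(region)
    x = trace.positions[sl]
    y = np.clip(trace.absorbance[sl] - trace.baseline, 0.0, None)
    if len(x) < 3:
        raise ValueError(f"region {region!r} has {len(x)} sample points; need >= 3")
    n_intervals = len(x) - 1
    if n_intervals % 2 == 0:
        return float(simpson(y, x=x))
    area = float(simpson(y[:-1], x=x[:-1]))
    area += float(trapezoid(y[-2:], x=x[-2:]))
    return area


def pm_ratio(trace: AbsorbanceTrace) -> float:
    """Polysome:monosome ratio of Simpson areas; monosome area must be > 0."""
    for required in ("monosome_80S", "polysome"):
        if required not in trace.regions:
            raise KeyError(f"trace lacks required region {required!r}")
    mono = simpson_auc(trace, "monosome_80S")
    poly = simpson_auc(trace, "polysome")
    if mono <= 0:
        raise ValueError("monosome area <= 0; P/M ratio undefined")
    return poly / mono


def region_area_table(trace: AbsorbanceTrace):
    """Per-region Simpson areas as a DataFrame (plus P/M when both regions exist)."""
    import pandas as pd

    rows = [
        {"region": name, "area": simpson_auc(trace, name)} for name in sorted(trace.regions)
    ]
    df = pd.DataFrame(rows)
    if {"monosome_80S", "polysome"} <= set(trace.regions):
        df.attrs["pm_ratio"] = pm_ratio(trace)
    return df
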