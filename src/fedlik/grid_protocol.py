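"""Round-1 coordination: the shared parameter lattice.

The coordinator collects each site's Wald confidence intervals, takes the
most conservative bound in each direction per parameter (the smallest lower
bound and the largest upper bound across sites), and segments the resulting
interval into a uniform lattice.  Because every site's interval is contained
in the conservative envelope, no plausible parameter value is excluded from
the search.

Axes are anchored at the exact, unrounded lower bound and generated by
integer indexing (``lower + k * increment``), never by repeated addition, so
the lattice is bit-reproducible across runs and platforms.  Grid alignment
between sites is validated through a fingerprint over the axis metadata —
never by float comparison of whole vectors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ModelMismatchError
from .glm_core import LocalFit

__all__ = [
    "ParameterAxis",
    "GridSpec",
    "conservative_bounds",
    "build_axis",
    "build_grid_spec",
    "grid_size",
]


@dataclass(frozen=True)
class ParameterAxis:
    """One uniformly spaced candidate-value vector for a single coefficient."""

    name: str
    lower: float
    upper: float
    increment: float

    def __post_init__(self):
        if self.increment <= 0:
            raise ValueError(f"axis {self.name!r}: increment must be > 0")
        if self.lower >= self.upper:
            raise ValueError(
                f"axis {self.name!r}: lower {self.lower} must be < upper {self.upper}"
            )

    @property
    def n_values(self) -> int:
        return int(np.floor((self.upper - self.lower) / self.increment + 1e-9)) + 1

    @property
    def values(self) -> np.ndarray:
        """``values[k] = lower + k * increment``, stopping at the last value
        that does not exceed ``upper`` (within 1e-9 slack)."""
        return self.lower + np.arange(self.n_values) * self.increment


@dataclass(frozen=True)
class GridSpec:
    """The shared evaluation lattice: one axis per model parameter, in
    parameter order, all axes sharing one increment."""

    axes: tuple[ParameterAxis, ...]
    increment: float
    fingerprint: str = field(default="", compare=False)

    def __post_init__(self):
        object.__setattr__(self, "axes", tuple(self.axes))
        if not self.axes:
            raise ValueError("a grid needs at least one axis")
        for ax in self.axes:
            if ax.increment != self.increment:
                raise ValueError(
                    f"axis {ax.name!r} increment {ax.increment} differs from the "
                    f"grid increment {self.increment}"
                )
        object.__setattr__(self, "fingerprint", self._digest())

    def _digest(self) -> str:
        # full-precision decimal text of the unrounded bounds; any change in
        # an axis name, bound or the increment changes the digest
        canon = {
            "increment": repr(self.increment),
            "axes": [
                {"name": a.name, "lower": repr(a.lower), "upper": repr(a.upper)}
                for a in self.axes
            ],
        }
        blob = json.dumps(canon, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(a.n_values for a in self.axes)

    def axis_values(self) -> tuple[np.ndarray, ...]:
        return tuple(a.values for a in self.axes)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema": "fedlik.grid_spec/1",
            "increment": self.increment,
            "axes": [
                {"name": a.name, "lower": a.lower, "upper": a.upper}
                for a in self.axes
            ],
            "fingerprint": self.fingerprint,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GridSpec":
        text = source if isinstance(source, str) and source.lstrip().startswith(
            "{"
        ) else Path(source).read_text()
        d = json.loads(text)
        spec = cls(
            axes=tuple(
                ParameterAxis(a["name"], a["lower"], a["upper"], d["increment"])
                for a in d["axes"]
            ),
            increment=d["increment"],
        )
        if d.get("fingerprint") and d["fingerprint"] != spec.fingerprint:
            raise ValueError("grid fingerprint does not match its axis metadata")
        return spec


def conservative_bounds(cis: list[tuple[float, float]]) -> tuple[float, float]:
    """Envelope of regional confidence intervals for one parameter.

    Returns ``(min of lower bounds, max of upper bounds)`` so that every
    input interval is contained in the result.
    """
    if not cis:
        raise ValueError("need at least one confidence interval")
    for lo, hi in cis:
        if not lo < hi:
            raise ValueError(f"invalid interval ({lo}, {hi}): lower must be < upper")
    return min(lo for lo, _ in cis), max(hi for _, hi in cis)


def build_axis(
    lower: float, upper: float, increment: float, name: str = ""
) -> ParameterAxis:
    """Segment ``[lower, upper]`` at uniform ``increment`` starting exactly
    at ``lower``."""
    return ParameterAxis(name=name, lower=float(lower), upper=float(upper),
                         increment=float(increment))


def build_grid_spec(fits: list[LocalFit], increment: float) -> GridSpec:
    """Build the shared lattice from regional confidence intervals.

    One axis per parameter: the conservative envelope of the sites' Wald
    intervals, segmented at ``increment``.  All fits must be converged and
    share an identical parameter set and order.
    """
    if not fits:
        raise ValueError("need at least one local fit")
    names = fits[0].parameter_names
    for f in fits[1:]:
        if f.parameter_names != names:
            raise ModelMismatchError(
                f"sites {fits[0].site_id!r} and {f.site_id!r} disagree on model "
                f"structure ({names} vs {f.parameter_names}); a valid joint "
                "likelihood requires an identical model structure at every site"
            )
    for f in fits:
        if not f.converged:
            raise ValueError(f"site {f.site_id!r}: fit did not converge")
    axes = []
    for j, name in enumerate(names):
        lo, hi = conservative_bounds(
            [(float(f.ci_lower[j]), float(f.ci_upper[j])) for f in fits]
        )
        axes.append(build_axis(lo, hi, increment, name=name))
    return GridSpec(axes=tuple(axes), increment=float(increment))


def grid_size(spec: GridSpec) -> int:
    """Total number of lattice cells (product of axis lengths; exact integer
    arithmetic, no overflow)."""
    size = 1
    for a in spec.axes:
        size *= a.n_values
    return size
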