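"""Depth profiles of membrane observables and control-vs-retinoid comparison.

Spin labels report from known depths: the headgroup label (T-PC) probes the
polar surface, the chain labels n-PC (n ∈ {5, 7, 10, 12, 16}) probe carbon
n of the stearoyl chain, ordered surface → center.  A profile collects one
observable (2Azz polarity, order parameter, τ, ...) across these positions
with replicate statistics; two profiles (control vs retinoid-containing
membranes) are compared per depth with Welch's two-sample t-test and the
study's significance tiers: ``*`` for p < 0.05, ``**`` for p < 0.02.

No correction for testing across multiple depths is applied by default
(matching the per-depth starring convention); Holm correction is available
behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .observables import ObservableSet
from .spectrum import SPIN_LABELS, Spectrum

__all__ = [
    "LabelPosition",
    "DepthProfile",
    "ProfilePoint",
    "ProfileComparison",
    "ProfileError",
    "LABEL_ORDER",
    "depth_annotation",
    "build_profile",
    "compare_profiles",
    "render_profile_table",
]

LabelPosition = Union[str, int]  # "T" or chain carbon number

#: Surface-to-center ordering of label positions.
LABEL_ORDER: tuple[LabelPosition, ...] = ("T", 5, 7, 10, 12, 16)

_STAR_P = 0.05
_DOUBLE_STAR_P = 0.02


class ProfileError(ValueError):
    """Inconsistent profile inputs."""


def position_from_label(spin_label: str) -> LabelPosition:
    """Map a spin-label name ('T-PC', '5-PC', ...) to its depth position."""
    if spin_label not in SPIN_LABELS:
        raise ProfileError(
            f"unknown spin label {spin_label!r}; expected one of {SPIN_LABELS}"
        )
    prefix = spin_label.split("-")[0]
    return "T" if prefix == "T" else int(prefix)


def depth_annotation(position: LabelPosition) -> str:
    if position == "T":
        return "polar headgroup region"
    return f"carbon {position} of the stearoyl chain"


@dataclass
class ProfilePoint:
    values: tuple[float, ...]
    mean: float
    sd: Optional[float]  # None when a single replicate makes sd undefined
    n_replicates: int


@dataclass
class DepthProfile:
    membrane_class: str
    condition: str
    observable: str
    points: dict[LabelPosition, ProfilePoint]

    @property
    def positions(self) -> list[LabelPosition]:
        return [p for p in LABEL_ORDER if p in self.points]


def _point(values: Sequence[float]) -> ProfilePoint:
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return ProfilePoint(
        values=tuple(float(v) for v in arr),
        mean=float(arr.mean()),
        sd=sd,
        n_replicates=int(arr.size),
    )


def build_profile(
    records: Iterable[tuple[Spectrum, ObservableSet]],
    observable: str,
) -> DepthProfile:
    """Group per-spectrum observables by label depth into a profile.

    All spectra must share membrane class and retinoid condition; the
    requested ``observable`` must be an :class:`ObservableSet` attribute
    (e.g. ``"two_A_zz"``, ``"S"``, ``"tau_2C"``).
    """
    records = list(records)
    if not records:
        raise ProfileError("no spectra supplied")
    classes = {spec.meta.membrane_class for spec, _ in records}
    conditions = {spec.meta.retinoid_condition for spec, _ in records}
    if len(classes) > 1:
        raise ProfileError(f"mixed membrane classes {sorted(classes)}")
    if len(conditions) > 1:
        raise ProfileError(f"mixed conditions {sorted(conditions)}")
    grouped: dict[LabelPosition, list[float]] = {}
    for spec, obs in records:
        position = position_from_label(spec.meta.spin_label)
        value = getattr(obs, observable)
        if value is None:
            raise ProfileError(
                f"observable {observable!r} missing for a {spec.meta.spin_label} spectrum"
            )
        grouped.setdefault(position, []).append(float(value))
    points = {
        pos: _point(vals)
        for pos, vals in sorted(
            grouped.items(), key=lambda kv: LABEL_ORDER.index(kv[0])
        )
    }
    return DepthProfile(
        membrane_class=classes.pop(),
        condition=conditions.pop(),
        observable=observable,
        points=points,
    )


@dataclass
class ComparisonPoint:
    delta: float  # treated mean - control mean
    p_value: Optional[float]  # None when replicates are insufficient
    tier: str  # "none" | "star" | "double_star" | "insufficient_replicates"


@dataclass
class ProfileComparison:
    observable: str
    membrane_class: str
    control_condition: str
    treated_condition: str
    per_depth: dict[LabelPosition, ComparisonPoint]


def _welch_p(a: Sequence[float], b: Sequence[float]) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # Degenerate zero-variance case: identical constants are not a
        # difference; distinct constants are an exact one.
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def _tier(p: float) -> str:
    if p < _DOUBLE_STAR_P:
        return "double_star"
    if p < _STAR_P:
        return "star"
    return "none"


def _holm(pvals: Mapping[LabelPosition, float]) -> dict[LabelPosition, float]:
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted: dict[LabelPosition, float] = {}
    running = 0.0
    for rank, (pos, p) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adjusted[pos] = running
    return adjusted


def compare_profiles(
    control: DepthProfile,
    treated: DepthProfile,
    holm_correction: bool = False,
) -> ProfileComparison:
    """Per-depth Welch t-test between control and treated profiles."""
    if control.observable != treated.observable:
        raise ProfileError(
            f"observable mismatch: {control.observable} vs {treated.observable}"
        )
    if control.membrane_class != treated.membrane_class:
        raise ProfileError(
            f"membrane mismatch: {control.membrane_class} vs {treated.membrane_class}"
        )
    if set(control.points) != set(treated.points):
        raise ProfileError(
            f"label positions differ: {sorted(map(str, control.points))} vs "
            f"{sorted(map(str, treated.points))}"
        )
    raw_p: dict[LabelPosition, Optional[float]] = {}
    deltas: dict[LabelPosition, float] = {}
    for pos in control.positions:
        c, t = control.points[pos], treated.points[pos]
        deltas[pos] = t.mean - c.mean
        if c.n_replicates < 2 or t.n_replicates < 2:
            raw_p[pos] = None
        else:
            raw_p[pos] = _welch_p(c.values, t.values)
    defined = {pos: p for pos, p in raw_p.items() if p is not None}
    effective = _holm(defined) if holm_correction else defined
    per_depth = {}
    for pos in control.positions:
        p = raw_p[pos]
        if p is None:
            per_depth[pos] = ComparisonPoint(deltas[pos], None, "insufficient_replicates")
        else:
            per_depth[pos] = ComparisonPoint(deltas[pos], p, _tier(effective[pos]))
    return ProfileComparison(
        observable=control.observable,
        membrane_class=control.membrane_class,
        control_condition=control.condition,
        treated_condition=treated.condition,
        per_depth=per_depth,
    )


_POLARITY_NOTE = (
    "# note: 2Azz increases with local polarity (hydration); polarity-profile "
    "plots are conventionally drawn with this axis inverted, so that upward "
    "changes on such plots indicate a decrease in polarity"
)

_TIER_MARK = {"none": "", "star": "*", "double_star": "**",
              "insufficient_replicates": "n/a"}


def render_profile_table(
    control: DepthProfile,
    treated: Optional[DepthProfile] = None,
    comparison: Optional[ProfileComparison] = None,
    sep: str = "\t",
) -> str:
    """Delimited profile table (one row per depth), with polarity orientation note."""
    rows = []
    for pos in control.positions:
        c = control.points[pos]
        row = {
            "position": pos,
            "depth": depth_annotation(pos),
            "control_mean": c.mean,
            "control_sd": c.sd if c.sd is not None else float("nan"),
            "control_n": c.n_replicates,
        }
        if treated is not None and pos in treated.points:
            t = treated.points[pos]
            row |= {
                "treated_mean": t.mean,
                "treated_sd": t.sd if t.sd is not None else float("nan"),
                "treated_n": t.n_replicates,
            }
        if comparison is not None and pos in comparison.per_depth:
            point = comparison.per_depth[pos]
            row |= {
                "delta": point.delta,
                "p_value": point.p_value if point.p_value is not None else float("nan"),
                "significance": _TIER_MARK[point.tier],
            }
        rows.append(row)
    frame = pd.DataFrame(rows)
    header = [f"# observable: {control.observable}",
              f"# membrane: {control.membrane_class}"]
    if "two_A_zz" in control.observable or "polarity" in control.observable:
        header.append(_POLARITY_NOTE)
    table = frame.to_csv(sep=sep, index=False, float_format="%.6g") if rows else ""
    if not rows:
        table = sep.join(
            ["position", "depth", "control_mean", "control_sd", "control_n"]
        ) + "\n"
    return "\n".join(header) + "\n" + table
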