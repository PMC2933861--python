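"""Scaffold-layout quality control from windowed composition profiles.

Pseudomolecules are built by ordering and orienting shotgun scaffolds. Where
marker resolution is poor (centromeres, pericentromeres), smooth large-scale
composition gradients — windowed binding energy, GC, or delta* — provide an
independent check: a break in a gradient is unlikely to fall by chance exactly
at a scaffold boundary. This module scores such breaks (junction
discontinuities) and evaluates whether reversing a scaffold's orientation
would reduce them.

Because the supported metrics are strand symmetric, reversing a scaffold is
modeled exactly by reversing the order of its windows; the sequence is never
re-read. Profiles computed from non-symmetrized signatures are refused.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LayoutError
from .signature import WindowProfile

__all__ = [
    "Placement",
    "AssemblyLayout",
    "JunctionScore",
    "FlipSuggestion",
    "read_layout",
    "junction_discontinuities",
    "evaluate_flip",
    "suggest_flips",
    "default_flip_threshold",
    "region_stats",
    "apply_flips",
]

_GAP_TYPES = {"N", "U"}


@dataclass(frozen=True)
class Placement:
    """One component (scaffold slice or gap) placed on an object.

    Coordinates are 0-based half-open on the object (pseudomolecule).
    """

    object_id: str
    object_start: int
    object_end: int
    component_id: Optional[str]
    orientation: str = "+"
    component_type: str = "sequence"  # "sequence" | "gap"
    gap_length: int = 0

    @property
    def is_gap(self) -> bool:
        return self.component_type == "gap"


@dataclass
class AssemblyLayout:
    """Ordered, oriented scaffold placements tiling one or more objects."""

    placements: List[Placement]

    def __post_init__(self) -> None:
        problems = []
        by_object: Dict[str, List[Placement]] = {}
        for p in self.placements:
            by_object.setdefault(p.object_id, []).append(p)
        for obj, rows in by_object.items():
            for i, p in enumerate(rows):
                if p.object_end <= p.object_start:
                    problems.append(f"{obj}: empty/negative interval at part {i + 1}")
                if i and p.object_start != rows[i - 1].object_end:
                    problems.append(
                        f"{obj}: parts {i} and {i + 1} do not tile contiguously "
                        f"({rows[i - 1].object_end} vs {p.object_start})"
                    )
        if problems:
            raise LayoutError("invalid layout:\n" + "\n".join(problems))

    def objects(self) -> List[str]:
        seen = dict.fromkeys(p.object_id for p in self.placements)
        return list(seen)

    def scaffolds(self, object_id: str) -> List[Placement]:
        """Sequence placements of one object, in object order."""
        rows = [
            p
            for p in self.placements
            if p.object_id == object_id and not p.is_gap
        ]
        if not rows:
            raise LayoutError(f"object {object_id!r} not in layout")
        return rows

    def scaffold(self, scaffold_id: str) -> Placement:
        rows = [p for p in self.placements if p.component_id == scaffold_id]
        if not rows:
            raise LayoutError(f"scaffold {scaffold_id!r} not in layout")
        if len(rows) > 1:
            raise LayoutError(f"scaffold {scaffold_id!r} placed more than once")
        return rows[0]


@dataclass(frozen=True)
class JunctionScore:
    """Composition discontinuity at one scaffold-scaffold junction.

    ``discontinuity`` is |mean of k windows left - mean of k windows right|,
    using only windows fully inside the flanking scaffolds (windows straddling
    the junction are excluded); NaN when fewer than k non-missing windows
    survive on either side.
    """

    object_id: str
    junction_position: int
    left_scaffold: str
    right_scaffold: str
    discontinuity: float
    k: int


@dataclass(frozen=True)
class FlipSuggestion:
    """Outcome of evaluating an orientation flip for one scaffold."""

    scaffold_id: str
    score_current: float
    score_flipped: float
    improvement: float
    suggested: bool
    metric: str
    low_confidence: bool = False


def _parse_agp(lines: Sequence[str], path: str) -> List[Placement]:
    placements = []
    problems = []
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            problems.append(f"{path}:{lineno}: fewer than 8 columns")
            continue
        obj, beg, end, _part, ctype = cols[0], cols[1], cols[2], cols[3], cols[4]
        try:
            start = int(beg) - 1  # AGP is 1-based inclusive
            stop = int(end)
        except ValueError:
            problems.append(f"{path}:{lineno}: non-integer coordinates")
            continue
        if ctype in _GAP_TYPES:
            placements.append(
                Placement(
                    object_id=obj,
                    object_start=start,
                    object_end=stop,
                    component_id=None,
                    component_type="gap",
                    gap_length=stop - start,
                )
            )
        else:
            if len(cols) < 9:
                problems.append(f"{path}:{lineno}: sequence row needs 9 columns")
                continue
            orientation = cols[8] if cols[8] in {"+", "-"} else "+"
            placements.append(
                Placement(
                    object_id=obj,
                    object_start=start,
                    object_end=stop,
                    component_id=cols[5],
                    orientation=orientation,
                    component_type="sequence",
                )
            )
    if problems:
        raise LayoutError("bad AGP:\n" + "\n".join(problems))
    return placements


def _parse_bed(lines: Sequence[str], path: str) -> List[Placement]:
    rows = []
    problems = []
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            problems.append(f"{path}:{lineno}: fewer than 3 columns")
            continue
        try:
            start, stop = int(cols[1]), int(cols[2])
        except ValueError:
            problems.append(f"{path}:{lineno}: non-integer coordinates")
            continue
        name = cols[3] if len(cols) > 3 else f"{cols[0]}:{start}-{stop}"
        strand = cols[5] if len(cols) > 5 and cols[5] in {"+", "-"} else "+"
        rows.append(
            Placement(
                object_id=cols[0],
                object_start=start,
                object_end=stop,
                component_id=name,
                orientation=strand,
                component_type="sequence",
            )
        )
    if problems:
        raise LayoutError("bad BED:\n" + "\n".join(problems))
    # BED files need not state gaps; synthesize gap placements for holes.
    rows.sort(key=lambda p: (p.object_id, p.object_start))
    filled: List[Placement] = []
    for p in rows:
        if filled and filled[-1].object_id == p.object_id:
            prev_end = filled[-1].object_end
            if p.object_start < prev_end:
                raise LayoutError(
                    f"{path}: overlapping components on {p.object_id} "
                    f"({filled[-1].component_id} and {p.component_id})"
                )
            if p.object_start > prev_end:
                filled.append(
                    Placement(
                        object_id=p.object_id,
                        object_start=prev_end,
                        object_end=p.object_start,
                        component_id=None,
                        component_type="gap",
                        gap_length=p.object_start - prev_end,
                    )
                )
        filled.append(p)
    return filled


def read_layout(
    path,
    fasta_lengths: Optional[Mapping[str, int]] = None,
    fmt: Optional[str] = None,
) -> AssemblyLayout:
    """Read an AGP v2.0 or BED scaffold layout into 0-based half-open form.

    Format is taken from ``fmt`` ("agp"/"bed") or guessed from the file
    extension, falling back to column sniffing. With ``fasta_lengths`` the
    object extents are validated against the sequence lengths.
    """
    path = str(path)
    with open(path) as handle:
        lines = handle.readlines()
    if fmt is None:
        lower = path.lower()
        if lower.endswith(".agp"):
            fmt = "agp"
        elif lower.endswith(".bed"):
            fmt = "bed"
        else:
            data_cols = [
                ln.split("\t")
                for ln in lines
                if ln.strip() and not ln.startswith("#")
            ]
            fmt = "agp" if data_cols and len(data_cols[0]) >= 8 else "bed"
    if fmt == "agp":
        placements = _parse_agp(lines, path)
    elif fmt == "bed":
        placements = _parse_bed(lines, path)
    else:
        raise ConfigurationError(f"unknown layout format {fmt!r}")
    layout = AssemblyLayout(placements)
    if fasta_lengths is not None:
        problems = []
        for obj in layout.objects():
            if obj not in fasta_lengths:
                problems.append(f"object {obj!r} missing from FASTA")
                continue
            extent = max(
                p.object_end for p in layout.placements if p.object_id == obj
            )
            if extent > fasta_lengths[obj]:
                problems.append(
                    f"object {obj!r} layout extends to {extent} but sequence "
                    f"is {fasta_lengths[obj]} bases"
                )
        if problems:
            raise LayoutError("layout/FASTA mismatch:\n" + "\n".join(problems))
    return layout


def _inside_window_indices(
    profile: WindowProfile, start: int, end: int
) -> np.ndarray:
    """Indices of windows fully within [start, end)."""
    starts, ends = profile.starts, profile.ends
    return np.flatnonzero((starts >= start) & (ends <= end))


def _side_mean(values: np.ndarray, idx: np.ndarray, k: int, tail: str) -> float:
    """Mean of the last/first k finite values among windows ``idx``."""
    finite = idx[np.isfinite(values[idx])]
    if finite.size < k:
        return float("nan")
    chosen = finite[-k:] if tail == "last" else finite[:k]
    return float(values[chosen].mean())


def junction_discontinuities(
    profile: WindowProfile,
    layout: AssemblyLayout,
    k: int = 3,
) -> List[JunctionScore]:
    """Score the profile discontinuity at every scaffold-scaffold junction.

    Gaps between scaffolds do not form junctions of their own; the junction is
    between the flanking scaffolds and located at the left scaffold's end.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    scaffolds = layout.scaffolds(profile.sequence_id)
    values = profile.values
    scores = []
    for left, right in zip(scaffolds[:-1], scaffolds[1:]):
        left_idx = _inside_window_indices(profile, left.object_start, left.object_end)
        right_idx = _inside_window_indices(
            profile, right.object_start, right.object_end
        )
        mean_left = _side_mean(values, left_idx, k, "last")
        mean_right = _side_mean(values, right_idx, k, "first")
        scores.append(
            JunctionScore(
                object_id=profile.sequence_id,
                junction_position=left.object_end,
                left_scaffold=str(left.component_id),
                right_scaffold=str(right.component_id),
                discontinuity=abs(mean_left - mean_right),
                k=k,
            )
        )
    return scores


def default_flip_threshold(profile: WindowProfile) -> float:
    """2x the median absolute successive-window difference (robust noise scale)."""
    v = profile.values
    both = np.isfinite(v[:-1]) & np.isfinite(v[1:])
    if not both.any():
        return 0.0
    return 2.0 * float(np.median(np.abs(np.diff(v))[both]))


def _junction_scores_for(
    values: np.ndarray,
    profile: WindowProfile,
    inside: np.ndarray,
    neighbors: List[Tuple[Placement, str]],
    k: int,
) -> List[float]:
    out = []
    for neighbor, side in neighbors:
        n_idx = _inside_window_indices(
            profile, neighbor.object_start, neighbor.object_end
        )
        if side == "left":
            a = _side_mean(values, n_idx, k, "last")
            b = _side_mean(values, inside, k, "first")
        else:
            a = _side_mean(values, inside, k, "last")
            b = _side_mean(values, n_idx, k, "first")
        out.append(abs(a - b))
    return out


def evaluate_flip(
    profile: WindowProfile,
    layout: AssemblyLayout,
    scaffold_id: str,
    k: int = 3,
    threshold: Optional[float] = None,
) -> FlipSuggestion:
    """Compare junction discontinuities before and after reversing one scaffold.

    The flip is modeled by reversing the order of the windows fully inside the
    scaffold (exact for strand-symmetric metrics); windows straddling the
    scaffold ends are excluded from both evaluations. A junction that cannot
    be scored in either orientation is dropped from both sums. Scaffolds
    spanning fewer than 2k windows yield a low-confidence, never-suggested
    result. ``suggested`` requires improvement > threshold (default: 2x the
    profile's median absolute successive difference).
    """
    if not profile.strand_symmetric:
        raise ConfigurationError(
            "flip evaluation requires a strand-symmetric metric; recompute the "
            "profile with a symmetrized signature"
        )
    if threshold is None:
        threshold = default_flip_threshold(profile)
    placement = layout.scaffold(scaffold_id)
    if placement.object_id != profile.sequence_id:
        raise LayoutError(
            f"scaffold {scaffold_id!r} lies on {placement.object_id!r}, "
            f"profile on {profile.sequence_id!r}"
        )
    scaffolds = layout.scaffolds(profile.sequence_id)
    pos = next(i for i, p in enumerate(scaffolds) if p.component_id == scaffold_id)
    neighbors: List[Tuple[Placement, str]] = []
    if pos > 0:
        neighbors.append((scaffolds[pos - 1], "left"))
    if pos < len(scaffolds) - 1:
        neighbors.append((scaffolds[pos + 1], "right"))

    inside = _inside_window_indices(
        profile, placement.object_start, placement.object_end
    )
    low_confidence = inside.size < 2 * k
    current = profile.values
    flipped = current.copy()
    flipped[inside] = flipped[inside][::-1]

    cur_scores = _junction_scores_for(current, profile, inside, neighbors, k)
    flip_scores = _junction_scores_for(flipped, profile, inside, neighbors, k)
    usable = [
        (c, f)
        for c, f in zip(cur_scores, flip_scores)
        if np.isfinite(c) and np.isfinite(f)
    ]
    if not usable:
        return FlipSuggestion(
            scaffold_id=scaffold_id,
            score_current=float("nan"),
            score_flipped=float("nan"),
            improvement=float("nan"),
            suggested=False,
            metric=profile.metric,
            low_confidence=True,
        )
    score_current = float(sum(c for c, _ in usable))
    score_flipped = float(sum(f for _, f in usable))
    improvement = score_current - score_flipped
    return FlipSuggestion(
        scaffold_id=scaffold_id,
        score_current=score_current,
        score_flipped=score_flipped,
        improvement=improvement,
        suggested=bool(not low_confidence and improvement > threshold),
        metric=profile.metric,
        low_confidence=low_confidence,
    )


def suggest_flips(
    profile: WindowProfile,
    layout: AssemblyLayout,
    k: int = 3,
    threshold: Optional[float] = None,
) -> List[FlipSuggestion]:
    """Evaluate a flip for every scaffold placed on the profiled object."""
    if threshold is None:
        threshold = default_flip_threshold(profile)
    return [
        evaluate_flip(profile, layout, str(p.component_id), k=k, threshold=threshold)
        for p in layout.scaffolds(profile.sequence_id)
    ]


def apply_flips(layout: AssemblyLayout, scaffold_ids: Sequence[str]) -> AssemblyLayout:
    """Return a layout with the given scaffolds' orientations toggled."""
    flip = set(scaffold_ids)
    rows = [
        replace(p, orientation="-" if p.orientation == "+" else "+")
        if p.component_id in flip
        else p
        for p in layout.placements
    ]
    return AssemblyLayout(rows)


def region_stats(
    profile: WindowProfile, boundaries: Sequence[int]
) -> pd.DataFrame:
    """Per-region mean, sample SD (n-1), and window count of a profile.

    ``boundaries`` are sorted cut positions partitioning the profiled extent
    into len(boundaries)+1 regions; each window is assigned to the region
    containing its midpoint, and missing windows are excluded. Empty regions
    are reported with n == 0.
    """
    extent = int(profile.ends[-1]) if profile.n_windows else 0
    bounds = list(boundaries)
    if bounds != sorted(bounds):
        raise ConfigurationError("boundaries must be sorted")
    if any(b < 0 or b > extent for b in bounds):
        raise ConfigurationError(
            f"boundaries must lie within [0, {extent}] (profile extent)"
        )
    edges = [0] + bounds + [extent]
    mid = profile.midpoints()
    rows = []
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        in_region = (mid >= lo) & (mid < hi) if hi < extent else (mid >= lo) & (
            mid <= hi
        )
        vals = profile.values[in_region]
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "region": i,
                "start": lo,
                "end": hi,
                "n": int(vals.size),
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
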