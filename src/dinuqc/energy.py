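"""Nearest-neighbor DNA duplex free energies and windowed profiles.

The stability of double-stranded DNA is well approximated by summing a free
energy increment ΔG° (kcal/mol at 37°C) over each overlapping dinucleotide
step. Reverse-complement steps share one parameter, so the 16 dinucleotides
reduce to 10 unique pairs. The windowed binding energy of a sequence is the
mean ΔG° over all counted (non-N-adjacent) dinucleotides in the window; since
every ΔG° is negative, profiles report the positive magnitude by default,
which tracks (C+G) content almost perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._seq import DINUCS, encode, iter_window_counts, revcomp
from .errors import ConfigurationError, InsufficientDataError
from .signature import WindowProfile

__all__ = [
    "EnergyTable",
    "EnergyProfileOptions",
    "default_energy_table",
    "window_energy",
    "energy_profile",
    "gc_profile",
    "profile_correlation",
]

#: The 10 unique nearest-neighbor pairs, ΔG° in kcal/mol at 37°C.
_DEFAULT_ROWS: Tuple[Tuple[str, float], ...] = (
    ("AA/TT", -1.00),
    ("AC/GT", -1.44),
    ("AG/CT", -1.28),
    ("AT", -0.88),
    ("CA/TG", -1.45),
    ("CC/GG", -1.84),
    ("CG", -2.17),
    ("GC/GC", -2.24),
    ("GA/TC", -1.30),
    ("TA", -0.58),
)


@dataclass(frozen=True)
class EnergyTable:
    """ΔG° for all 16 dinucleotide steps, expanded from unique-pair labels.

    ``dg`` maps every dinucleotide to its (negative) free energy of binding;
    reverse-complement partners always share one value. ``source_pairs`` keeps
    the pair labels the table was built from.
    """

    dg: Mapping[str, float]
    source_pairs: Tuple[str, ...]

    def __post_init__(self) -> None:
        missing = [d for d in DINUCS if d not in self.dg]
        if missing:
            raise ConfigurationError(f"energy table missing entries: {missing}")
        for d in DINUCS:
            if self.dg[d] != self.dg[revcomp(d)]:
                raise ConfigurationError(
                    f"energy table breaks reverse-complement sharing at {d}"
                )
            if not self.dg[d] < 0:
                raise ConfigurationError(
                    f"free energy of binding must be negative (got {d}={self.dg[d]})"
                )

    def as_array(self) -> np.ndarray:
        """(16,) ΔG° vector in lexicographic dinucleotide order."""
        return np.array([self.dg[d] for d in DINUCS], dtype=float)

    @classmethod
    def from_pairs(cls, rows: Sequence[Tuple[str, float]]) -> "EnergyTable":
        """Build from (pair label, ΔG°) rows; labels like ``"CA/TG"`` or ``"AT"``."""
        dg: Dict[str, float] = {}
        labels = []
        for label, value in rows:
            labels.append(label)
            for member in label.split("/"):
                member = member.strip().upper()
                if len(member) != 2 or any(b not in "ACGT" for b in member):
                    raise ConfigurationError(f"bad pair label {label!r}")
                for d in (member, revcomp(member)):
                    if d in dg and dg[d] != value:
                        raise ConfigurationError(
                            f"conflicting values for {d}: {dg[d]} vs {value}"
                        )
                    dg[d] = float(value)
        return cls(dg=dg, source_pairs=tuple(labels))

    @classmethod
    def from_tsv(cls, path) -> "EnergyTable":
        """Load a two-column TSV: pair label, ΔG° (kcal/mol). '#' comments allowed."""
        rows = []
        with open(path) as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ConfigurationError(
                        f"{path}:{lineno}: expected 2 tab-separated columns"
                    )
                try:
                    rows.append((parts[0], float(parts[1])))
                except ValueError:
                    raise ConfigurationError(
                        f"{path}:{lineno}: not a number: {parts[1]!r}"
                    ) from None
        if not rows:
            raise ConfigurationError(f"{path}: no energy rows found")
        return cls.from_pairs(rows)


@lru_cache(maxsize=1)
def default_energy_table() -> EnergyTable:
    """The packaged consensus NN table (ΔG° at 37°C, kcal/mol)."""
    return EnergyTable.from_pairs(_DEFAULT_ROWS)


@dataclass(frozen=True)
class EnergyProfileOptions:
    """Windowing options for binding-energy profiles."""

    window_size: int = 50_000
    report_magnitude: bool = True
    step: Optional[int] = None

    def __post_init__(self) -> None:
        if self.window_size < 1_000:
            raise ConfigurationError("window_size must be >= 1000")
        if self.step is not None and self.step < 1:
            raise ConfigurationError("step must be >= 1")


def window_energy(
    sequence: str,
    table: Optional[EnergyTable] = None,
    report_magnitude: bool = True,
) -> float:
    """Mean NN free energy per counted dinucleotide of one sequence.

    Ns are ignored: pairs adjacent to an N contribute nothing to either the
    energy sum or the pair count. Returns NaN when no dinucleotide is counted.
    With ``report_magnitude`` the sign is flipped to a positive magnitude.
    """
    if table is None:
        table = default_energy_table()
    codes = encode(sequence)
    from ._seq import mono_pair_counts

    _, pair = mono_pair_counts(codes)
    total = pair.sum()
    if total == 0:
        return float("nan")
    value = float(pair @ table.as_array()) / float(total)
    return -value if report_magnitude else value


def energy_profile(
    record: str,
    options: Optional[EnergyProfileOptions] = None,
    sequence_id: str = "seq",
    table: Optional[EnergyTable] = None,
) -> WindowProfile:
    """Windowed mean binding energy along a sequence.

    Windowing contract matches :func:`dinuqc.signature.delta_profile`: windows
    with informative length below half the window size (or with no counted
    pair) are missing, and the terminal window may be short.
    """
    if options is None:
        options = EnergyProfileOptions()
    if table is None:
        table = default_energy_table()
    dg = table.as_array()
    step = options.step if options.step is not None else options.window_size
    codes = encode(record, name=sequence_id)
    windows, values, informative = [], [], []
    half = options.window_size / 2.0
    for start, end, _mono, pair, n_inf in iter_window_counts(
        codes, options.window_size, step
    ):
        windows.append((start, end))
        informative.append(n_inf)
        total = pair.sum()
        if n_inf < half or total == 0:
            values.append(np.nan)
            continue
        value = float(pair @ dg) / float(total)
        values.append(-value if options.report_magnitude else value)
    return WindowProfile(
        sequence_id=sequence_id,
        windows=windows,
        values=np.array(values, dtype=float),
        metric="binding_energy",
        window_size=options.window_size,
        step=step,
        strand_symmetric=True,
        informative=np.array(informative, dtype=np.int64),
    )


def gc_profile(
    record: str,
    window_size: int = 50_000,
    step: Optional[int] = None,
    sequence_id: str = "seq",
) -> WindowProfile:
    """Windowed (C+G) fraction: GC count over non-N count per window.

    A window with no informative base is missing.
    """
    if window_size < 1:
        raise ConfigurationError("window_size must be >= 1")
    if step is None:
        step = window_size
    codes = encode(record, name=sequence_id)
    windows, values, informative = [], [], []
    for start, end, mono, _pair, n_inf in iter_window_counts(codes, window_size, step):
        windows.append((start, end))
        informative.append(n_inf)
        if n_inf == 0:
            values.append(np.nan)
        else:
            values.append(float(mono[1] + mono[2]) / n_inf)
    return WindowProfile(
        sequence_id=sequence_id,
        windows=windows,
        values=np.array(values, dtype=float),
        metric="gc_fraction",
        window_size=window_size,
        step=step,
        strand_symmetric=True,
        informative=np.array(informative, dtype=np.int64),
    )


def profile_correlation(p: WindowProfile, q: WindowProfile) -> float:
    """Pearson correlation of two profiles on the same window grid.

    Windows missing in either profile are dropped pairwise; at least three
    shared windows must survive.
    """
    if p.windows != q.windows:
        raise ConfigurationError("profiles are on different window grids")
    mask = np.isfinite(p.values) & np.isfinite(q.values)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"only {int(mask.sum())} shared non-missing windows (need >= 3)"
        )
    r = stats.pearsonr(p.values[mask], q.values[mask]).statistic
    return float(r)
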