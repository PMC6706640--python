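"""Tabular inputs of the screen: peak lists, reference interactions,
chemical-similarity scores, and peak windows.

All tables are plain CSV with mandated column names so that exports from a
spreadsheet or a database dump drop straight in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

INTERACTION_TYPES = ("catalytic", "regulatory", "both")


@dataclass(frozen=True)
class MetabolitePeakList:
    """Reference peaks of one metabolite from its pure-compound spectrum.

    ``peaks`` is a tuple of (ppm, relative intensity) with the relative
    intensities normalised so the strongest peak is 1.
    """

    metabolite_id: str
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"peak list for {self.metabolite_id!r} is empty")
        if any(rel < 0 for _, rel in self.peaks):
            raise ValueError("relative intensities must be non-negative")
        top = max(rel for _, rel in self.peaks)
        if top <= 0:
            raise ValueError("at least one peak must have positive intensity")
        if abs(top - 1.0) > 1e-9:
            norm = tuple((p, rel / top) for p, rel in self.peaks)
            object.__setattr__(self, "peaks", norm)

    @property
    def ppms(self) -> tuple[float, ...]:
        return tuple(p for p, _ in self.peaks)


@dataclass(frozen=True)
class PeakWindow:
    """A ppm interval, free of cross-metabolite overlap within its mix,
    inside which one metabolite signal maximum is quantified."""

    metabolite_id: str
    mix_id: str
    ppm_lo: float
    ppm_hi: float
    source_peak_ppm: float

    def __post_init__(self) -> None:
        if not self.ppm_lo < self.ppm_hi:
            raise ValueError(
                f"window for {self.metabolite_id}: ppm_lo must be < ppm_hi "
                f"({self.ppm_lo} >= {self.ppm_hi})"
            )


@dataclass
class ReferenceSet:
    """Known protein-metabolite interactions (the benchmark ground truth).

    Entries are keyed on the (protein, metabolite) pair; a pair listed both
    as catalytic and regulatory collapses to type ``both``.
    """

    entries: dict = field(default_factory=dict)  # (protein_id, metabolite_id) -> type

    def __post_init__(self) -> None:
        for key, typ in self.entries.items():
            if typ not in INTERACTION_TYPES:
                raise ValueError(f"unknown interaction type {typ!r} for {key}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.entries

    def pairs(self) -> set:
        return set(self.entries)

    def type_of(self, protein_id: str, metabolite_id: str) -> str | None:
        return self.entries.get((protein_id, metabolite_id))

    def add(self, protein_id: str, metabolite_id: str, typ: str) -> None:
        if typ not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {typ!r}")
        key = (protein_id, metabolite_id)
        prev = self.entries.get(key)
        if prev is None or prev == typ:
            self.entries[key] = typ
        else:
            # catalytic + regulatory (in any order, or either with 'both')
            self.entries[key] = "both"


@dataclass
class SimilarityTable:
    """Maximum global chemical similarity between each metabolite and the
    substrates/products of each protein, on a [0, 1] scale.

    Produced upstream by a maximal-common-substructure comparison; this
    package only consumes the scores.
    """

    values: dict = field(default_factory=dict)  # (protein_id, metabolite_id) -> float

    def __post_init__(self) -> None:
        for key, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"similarity for {key} out of [0, 1]: {v}")

    def __len__(self) -> int:
        return len(self.values)

    def get(self, protein_id: str, metabolite_id: str) -> float | None:
        return self.values.get((protein_id, metabolite_id))


# ----------------------------------------------------------------------
# CSV readers/writers


def read_peak_lists(path: str | Path) -> dict[str, MetabolitePeakList]:
    """Read a peak-list CSV (metabolite_id, ppm, rel_intensity) into a dict
    keyed by metabolite id."""
    df = pd.read_csv(path)
    required = {"metabolite_id", "ppm", "rel_intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"peak list CSV must have columns {sorted(required)}")
    out: dict[str, MetabolitePeakList] = {}
    for met, grp in df.groupby("metabolite_id", sort=True):
        peaks = tuple(
            (float(r.ppm), float(r.rel_intensity)) for r in grp.itertuples(index=False)
        )
        out[str(met)] = MetabolitePeakList(str(met), peaks)
    return out


def write_peak_lists(peak_lists: dict[str, MetabolitePeakList], path: str | Path) -> None:
    rows = [
        {"metabolite_id": pl.metabolite_id, "ppm": p, "rel_intensity": rel}
        for pl in peak_lists.values()
        for p, rel in pl.peaks
    ]
    pd.DataFrame(rows, columns=["metabolite_id", "ppm", "rel_intensity"]).to_csv(
        path, index=False
    )


def read_reference_set(path: str | Path) -> ReferenceSet:
    """Read a known-interaction CSV (protein_id, metabolite_id, type).

    Duplicate rows for a pair are deduplicated; a pair listed as both
    catalytic and regulatory becomes type ``both``.
    """
    df = pd.read_csv(path)
    required = {"protein_id", "metabolite_id", "type"}
    if not required.issubset(df.columns):
        raise ValueError(f"reference CSV must have columns {sorted(required)}")
    ref = ReferenceSet()
    for row in df.itertuples(index=False):
        typ = str(row.type).strip().lower()
        if typ not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {row.type!r}")
        ref.add(str(row.protein_id), str(row.metabolite_id), typ)
    return ref


def write_reference_set(ref: ReferenceSet, path: str | Path) -> None:
    rows = [
        {"protein_id": p, "metabolite_id": m, "type": t}
        for (p, m), t in sorted(ref.entries.items())
    ]
    pd.DataFrame(rows, columns=["protein_id", "metabolite_id", "type"]).to_csv(
        path, index=False
    )


def read_similarity_table(path: str | Path) -> SimilarityTable:
    """Read a similarity CSV (protein_id, metabolite_id, max_similarity).

    Values outside [0, 1] and duplicate pairs are rejected.
    """
    df = pd.read_csv(path)
    required = {"protein_id", "metabolite_id", "max_similarity"}
    if not required.issubset(df.columns):
        raise ValueError(f"similarity CSV must have columns {sorted(required)}")
    values: dict = {}
    for row in df.itertuples(index=False):
        key = (str(row.protein_id), str(row.metabolite_id))
        if key in values:
            raise ValueError(f"duplicate similarity entry for pair {key}")
        values[key] = float(row.max_similarity)
    return SimilarityTable(values)


def write_similarity_table(table: SimilarityTable, path: str | Path) -> None:
    rows = [
        {"protein_id": p, "metabolite_id": m, "max_similarity": v}
        for (p, m), v in sorted(table.values.items())
    ]
    pd.DataFrame(rows, columns=["protein_id", "metabolite_id", "max_similarity"]).to_csv(
        path, index=False
    )


def read_windows(path: str | Path) -> list[PeakWindow]:
    df = pd.read_csv(path)
    required = {"metabolite_id", "mix_id", "ppm_lo", "ppm_hi", "source_peak_ppm"}
    if not required.issubset(df.columns):
        raise ValueError(f"windows CSV must have columns {sorted(required)}")
    return [
        PeakWindow(
            str(r.metabolite_id),
            str(r.mix_id),
            float(r.ppm_lo),
            float(r.ppm_hi),
            float(r.source_peak_ppm),
        )
        for r in df.itertuples(index=False)
    ]


def write_windows(windows: list[PeakWindow], path: str | Path) -> None:
    rows = [
        {
            "metabolite_id": w.metabolite_id,
            "mix_id": w.mix_id,
            "ppm_lo": w.ppm_lo,
            "ppm_hi": w.ppm_hi,
            "source_peak_ppm": w.source_peak_ppm,
        }
        for w in windows
    ]
    pd.DataFrame(
        rows, columns=["metabolite_id", "mix_id", "ppm_lo", "ppm_hi", "source_peak_ppm"]
    ).to_csv(path, index=False)
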