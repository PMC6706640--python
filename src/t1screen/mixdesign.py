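"""Metabolite mix design by simulated annealing.

Metabolites are screened in mixes, so every metabolite needs at least one
NMR signal that no co-mixed metabolite overlaps.  The designer partitions
the library into a fixed number of mixes by minimising a spectral-overlap
penalty: every same-mix pair of peaks from different metabolites closer
than the overlap range scores a fixed penalty (scaled by the product of the
relative peak intensities when intensity scoring is on).  A Metropolis
annealer with a linear cooling schedule and an optional exponential
refinement phase searches assignment space; pairs of metabolites that could
react enzymatically can be pinned to different mixes, and curated placements
can be forced outright.

Peak windows for quantification are then compiled per mix: each surviving
peak (no cross-metabolite neighbour within the overlap range) gets a window
of one overlap-range half-width on each side, truncated at the midpoint
between source peaks where adjacent windows would overlap, so windows are
pairwise disjoint within a mix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tables import MetabolitePeakList, PeakWindow

DEFAULT_OVERLAP_RANGE = 0.025
DEFAULT_SCORE_SCALING = 100.0


@dataclass(frozen=True)
class AnnealSchedule:
    """Annealing parameters.

    Defaults are a desk-scale schedule (20,000 steps, 3 restarts); the
    published large-scale settings (500,000 steps, 10 restarts) are
    available via :meth:`published`.
    """

    n_mixes: int = 4
    max_mix_size: int = 15
    cooling: str = "linear"
    start_temp: float = 10_000.0
    final_temp: float = 25.0
    max_steps: int = 20_000
    mix_rate: int = 2
    iterations: int = 3
    overlap_range: float = DEFAULT_OVERLAP_RANGE
    use_intensity_scoring: bool = True
    score_scaling: float = DEFAULT_SCORE_SCALING
    refine: bool = True
    refine_cooling: str = "exponential"
    refine_start_temp: float = 50.0
    refine_final_temp: float = 25.0
    refine_steps: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.start_temp > self.final_temp > 0:
            raise ValueError("need start_temp > final_temp > 0")
        if self.n_mixes < 1 or self.max_mix_size < 1:
            raise ValueError("n_mixes and max_mix_size must be positive")
        if self.cooling not in ("linear", "exponential"):
            raise ValueError("cooling must be 'linear' or 'exponential'")
        if self.mix_rate < 1 or self.max_steps < 1 or self.iterations < 1:
            raise ValueError("mix_rate, max_steps and iterations must be positive")

    @classmethod
    def published(cls, **overrides) -> "AnnealSchedule":
        """The large-scale schedule used for the 4x15 screening mixes."""
        base = dict(
            n_mixes=4,
            max_mix_size=15,
            cooling="linear",
            start_temp=10_000.0,
            final_temp=25.0,
            max_steps=500_000,
            mix_rate=2,
            iterations=10,
            overlap_range=0.025,
            use_intensity_scoring=True,
            score_scaling=100.0,
            refine=True,
            refine_cooling="exponential",
            refine_start_temp=50.0,
            refine_final_temp=25.0,
            refine_steps=1_000,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class MixDesign:
    """A mix partition: metabolite -> mix index (0-based), its overlap
    penalty, and (after window compilation) the per-mix peak windows."""

    assignment: dict
    score: float
    n_mixes: int
    windows: list = field(default_factory=list)

    def mix_members(self) -> list:
        out = [[] for _ in range(self.n_mixes)]
        for met, mx in sorted(self.assignment.items()):
            out[mx].append(met)
        return out

    def mix_id(self, met: str) -> str:
        return f"mix{self.assignment[met] + 1}"


# ----------------------------------------------------------------------
# Scoring


def _peak_arrays(peak_lists: dict):
    """Per-metabolite (ppm, intensity) arrays for vectorised scoring."""
    return {
        met: (
            np.array([p for p, _ in pl.peaks]),
            np.array([r for _, r in pl.peaks]),
        )
        for met, pl in peak_lists.items()
    }


def _mix_penalty(
    members,
    arrays,
    overlap_range: float,
    use_intensity: bool,
    scaling: float,
) -> float:
    if len(members) < 2:
        return 0.0
    ppm = np.concatenate([arrays[m][0] for m in members])
    rel = np.concatenate([arrays[m][1] for m in members])
    grp = np.concatenate(
        [np.full(len(arrays[m][0]), i) for i, m in enumerate(members)]
    )
    close = np.abs(ppm[:, None] - ppm[None, :]) < overlap_range
    cross = grp[:, None] != grp[None, :]
    mask = np.triu(close & cross, k=1)
    if not mask.any():
        return 0.0
    if use_intensity:
        weights = rel[:, None] * rel[None, :]
        return float(scaling * weights[mask].sum())
    return float(scaling * mask.sum())


def overlap_score(
    assignment: dict,
    peak_lists: dict,
    overlap_range: float = DEFAULT_OVERLAP_RANGE,
    use_intensity: bool = True,
    score_scaling: float = DEFAULT_SCORE_SCALING,
) -> float:
    """Total overlap penalty of an assignment; zero iff no same-mix pair of
    cross-metabolite peaks lies closer than the overlap range."""
    missing = [m for m in assignment if m not in peak_lists]
    if missing:
        raise ValueError(f"metabolites without peak lists: {missing}")
    arrays = _peak_arrays({m: peak_lists[m] for m in assignment})
    mixes: dict = {}
    for met, mx in assignment.items():
        mixes.setdefault(mx, []).append(met)
    return sum(
        _mix_penalty(members, arrays, overlap_range, use_intensity, score_scaling)
        for members in mixes.values()
    )


# ----------------------------------------------------------------------
# Annealer


def _initial_assignment(
    mets, schedule, must_separate, forced, rng, tries: int = 200
) -> dict:
    pair_conflicts: dict = {}
    for a, b in must_separate:
        pair_conflicts.setdefault(a, set()).add(b)
        pair_conflicts.setdefault(b, set()).add(a)
    for _ in range(tries):
        assignment = dict(forced)
        counts = [0] * schedule.n_mixes
        for met, mx in forced.items():
            counts[mx] += 1
        order = list(rng.permutation([m for m in mets if m not in forced]))
        ok = True
        for met in order:
            choices = [
                mx
                for mx in range(schedule.n_mixes)
                if counts[mx] < schedule.max_mix_size
                and all(
                    assignment.get(other) != mx
                    for other in pair_conflicts.get(met, ())
                )
            ]
            if not choices:
                ok = False
                break
            mx = int(rng.choice(choices))
            assignment[met] = mx
            counts[mx] += 1
        if ok:
            return assignment
    raise ValueError(
        "could not build a feasible initial assignment: constraints may be "
        "infeasible under the mix count and size cap"
    )


def _violates(assignment: dict, met: str, mx: int, conflicts: dict) -> bool:
    return any(assignment.get(other) == mx for other in conflicts.get(met, ()))


def _temperature(schedule_start, schedule_final, cooling, frac: float) -> float:
    if cooling == "linear":
        return schedule_start + (schedule_final - schedule_start) * frac
    return schedule_start * (schedule_final / schedule_start) ** frac


def anneal_mixes(
    peak_lists: dict,
    schedule: AnnealSchedule = AnnealSchedule(),
    must_separate=(),
    forced: dict | None = None,
) -> MixDesign:
    """Partition the library into mixes by simulated annealing.

    Moves relocate ``mix_rate`` random metabolites per step (swapping with a
    random occupant when the target mix is full); score decreases are always
    accepted, increases with probability exp(-delta/T).  The best design over
    all restarts is returned with its score recomputed from scratch; ties
    between equal-score designs break to the lexicographically smallest
    assignment in metabolite-id order.  Must-separate pairs and forced
    placements are honoured throughout.
    """
    forced = dict(forced or {})
    mets = sorted(peak_lists)
    if not mets:
        raise ValueError("empty metabolite library")
    if schedule.n_mixes * schedule.max_mix_size < len(mets):
        raise ValueError("library does not fit: n_mixes * max_mix_size too small")
    for a, b in must_separate:
        if a not in peak_lists or b not in peak_lists:
            raise ValueError(f"must-separate pair ({a}, {b}) outside the library")
        if a in forced and b in forced and forced[a] == forced[b]:
            raise ValueError(f"forced placement breaks must-separate pair ({a}, {b})")
    conflicts: dict = {}
    for a, b in must_separate:
        conflicts.setdefault(a, set()).add(b)
        conflicts.setdefault(b, set()).add(a)

    arrays = _peak_arrays(peak_lists)
    movable = [m for m in mets if m not in forced]

    def mix_lists(assignment):
        out = [[] for _ in range(schedule.n_mixes)]
        for met in mets:
            out[assignment[met]].append(met)
        return out

    def penalty(members):
        return _mix_penalty(
            members,
            arrays,
            schedule.overlap_range,
            schedule.use_intensity_scoring,
            schedule.score_scaling,
        )

    best_assignment: dict | None = None
    best_score = math.inf

    rng = np.random.default_rng(schedule.seed)
    for _ in range(schedule.iterations):
        assignment = _initial_assignment(mets, schedule, must_separate, forced, rng)
        mixes = mix_lists(assignment)
        mix_scores = [penalty(m) for m in mixes]
        score = sum(mix_scores)

        phases = [(schedule.cooling, schedule.start_temp, schedule.final_temp,
                   schedule.max_steps)]
        if schedule.refine:
            phases.append(
                (schedule.refine_cooling, schedule.refine_start_temp,
                 schedule.refine_final_temp, schedule.refine_steps)
            )
        for cooling, t_start, t_final, n_steps in phases:
            if score == 0 or not movable:
                break
            for step in range(n_steps):
                if score == 0:
                    break
                temp = _temperature(t_start, t_final, cooling,
                                    step / max(n_steps - 1, 1))
                k = min(schedule.mix_rate, len(movable))
                chosen = rng.choice(len(movable), size=k, replace=False)
                moves = []  # (met, from_mix, to_mix) incl. swap partners
                trial = dict(assignment)
                valid = True
                for ci in chosen:
                    met = movable[int(ci)]
                    src = trial[met]
                    dst = int(rng.integers(schedule.n_mixes - 1))
                    if dst >= src:
                        dst += 1
                    dst_members = [m for m in mets if trial[m] == dst]
                    if len(dst_members) >= schedule.max_mix_size:
                        # swap with a random movable occupant of the full mix
                        swap_pool = [m for m in dst_members if m not in forced]
                        if not swap_pool:
                            valid = False
                            break
                        partner = swap_pool[int(rng.integers(len(swap_pool)))]
                        trial[partner] = src
                        if _violates(trial, partner, src, conflicts):
                            valid = False
                            break
                        moves.append(partner)
                    trial[met] = dst
                    if _violates(trial, met, dst, conflicts):
                        valid = False
                        break
                    moves.append(met)
                if not valid:
                    continue
                touched = sorted(
                    {assignment[m] for m in moves} | {trial[m] for m in moves}
                )
                new_mixes = {
                    mx: [m for m in mets if trial[m] == mx] for mx in touched
                }
                delta = sum(penalty(new_mixes[mx]) - mix_scores[mx] for mx in touched)
                if delta <= 0 or rng.random() < math.exp(-delta / temp):
                    assignment = trial
                    for mx in touched:
                        mix_scores[mx] = penalty(new_mixes[mx])
                    score = sum(mix_scores)

        final_score = overlap_score(
            assignment,
            peak_lists,
            schedule.overlap_range,
            schedule.use_intensity_scoring,
            schedule.score_scaling,
        )
        key = tuple(assignment[m] for m in mets)
        if final_score < best_score or (
            final_score == best_score
            and best_assignment is not None
            and key < tuple(best_assignment[m] for m in mets)
        ):
            best_score = final_score
            best_assignment = dict(assignment)
        if best_score == 0:
            break

    assert best_assignment is not None
    return MixDesign(assignment=best_assignment, score=best_score,
                     n_mixes=schedule.n_mixes)


# ----------------------------------------------------------------------
# Peak-window compilation


def compile_peak_windows(
    design: MixDesign,
    peak_lists: dict,
    overlap_range: float = DEFAULT_OVERLAP_RANGE,
    min_window: float = 0.005,
) -> tuple[list, list]:
    """Compile quantification windows for every metabolite of every mix.

    A peak survives if its distance to every other-metabolite peak in the
    same mix exceeds the overlap range; its window spans one overlap range
    on each side of the catalogued shift.  Adjacent windows that would
    overlap are truncated at the midpoint between their source peaks (with a
    tiny guard gap) so windows stay pairwise disjoint; windows narrower than
    ``min_window`` after truncation are dropped.  Returns the windows plus
    the metabolites left with no window at all (a reported condition, not an
    error).
    """
    eps = 1e-6
    windows: list[PeakWindow] = []
    covered: set = set()
    for mx, members in enumerate(design.mix_members()):
        mix_id = f"mix{mx + 1}"
        candidates = []  # (ppm, met)
        for met in members:
            for p, _ in peak_lists[met].peaks:
                candidates.append((p, met))
        candidates.sort()
        for p, met in candidates:
            clashing = any(
                abs(p - q) <= overlap_range
                for q, other in candidates
                if other != met
            )
            if clashing:
                continue
            lo, hi = p - overlap_range, p + overlap_range
            # truncate against every neighbouring candidate window
            for q, other in candidates:
                if q == p and other == met:
                    continue
                mid = 0.5 * (p + q)
                if q < p:
                    lo = max(lo, mid + eps)
                else:
                    hi = min(hi, mid - eps)
            if hi - lo < min_window:
                continue
            windows.append(PeakWindow(met, mix_id, lo, hi, p))
            covered.add(met)
    uncovered = sorted(set(design.assignment) - covered)
    design.windows = windows
    return windows, uncovered
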