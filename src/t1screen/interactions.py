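"""Relaxation-factor quantification and the protein x metabolite matrix.

The relaxation factor compares the long/short spin-lock intensity ratio of
a metabolite alone with the same ratio in the protein's presence (after
subtracting the protein's own signal):

    ΔRF = M_long / M_short - (PM_long - P_long) / (PM_short - P_short)

A non-binder keeps its relaxation and gives ΔRF = 0; binding accelerates
relaxation in the PM sample and pushes ΔRF above zero.  One ΔRF per
qualifying peak is aggregated (mean by default) into one value per
protein-metabolite pair.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .processing import PeakQuant, Thresholds, calibrate_measurement, quantify_peak

AGGREGATION_POLICIES = ("mean", "median", "max")


class UnevaluablePeak(ValueError):
    """Raised when a peak's intensities cannot enter the relaxation factor
    (non-positive reference or protein-subtracted short-delay intensity)."""


@dataclass(frozen=True)
class RelaxationQuadruple:
    """The six window maxima entering one relaxation-factor evaluation
    (all on a common normalisation)."""

    m_short: float
    m_long: float
    p_short: float
    p_long: float
    pm_short: float
    pm_long: float

    @classmethod
    def from_quant(cls, q: PeakQuant) -> "RelaxationQuadruple":
        # the protein contribution was already subtracted pointwise from the
        # PM spectra before peak picking, so P enters as zero here
        return cls(
            m_short=q.i_m_short,
            m_long=q.i_m_long,
            p_short=0.0,
            p_long=0.0,
            pm_short=q.i_pmp_short,
            pm_long=q.i_pmp_long,
        )


def delta_rf(q: RelaxationQuadruple) -> float:
    """Relaxation factor difference for one peak.

    Positive values indicate faster metabolite relaxation in the protein's
    presence, i.e. binding.  Invariant under common rescaling of all six
    intensities.  Raises :class:`UnevaluablePeak` when a denominator is not
    positive rather than propagating a NaN.
    """
    if not q.m_short > 0:
        raise UnevaluablePeak("free-metabolite short-delay intensity must be positive")
    denom = q.pm_short - q.p_short
    if not denom > 0:
        raise UnevaluablePeak(
            "protein-subtracted short-delay intensity (PM_short - P_short) "
            f"must be positive (got {denom:.4g})"
        )
    return q.m_long / q.m_short - (q.pm_long - q.p_long) / denom


@dataclass(frozen=True)
class PeakOutcome:
    """Peak-level ΔRF with its QC flags, feeding pair aggregation."""

    delta_rf: float | None
    flags: frozenset
    replicate: int = 0

    def qualifies(self) -> bool:
        return not self.flags and self.delta_rf is not None


@dataclass(frozen=True)
class PairResult:
    protein_id: str
    metabolite_id: str
    delta_rf: float | None
    n_peaks_used: int
    replicate_values: tuple
    qc_flags: str


def aggregate_pair(
    protein_id: str,
    metabolite_id: str,
    peak_outcomes,
    policy: str = "mean",
) -> PairResult:
    """Combine peak-level ΔRF values into one pair value.

    Only peaks free of QC flags qualify.  Under the default ``mean`` policy
    the qualifying peaks are averaged within each measurement replicate and
    the replicate values averaged in turn; ``median`` and ``max`` apply the
    same two-level scheme with their respective statistic at the peak level.
    No qualifying peak at all yields a missing value with a QC summary.
    """
    if policy not in AGGREGATION_POLICIES:
        raise ValueError(f"unknown aggregation policy {policy!r}")
    outcomes = list(peak_outcomes)
    qualifying = [o for o in outcomes if o.qualifies()]
    if not qualifying:
        counts = Counter(flag for o in outcomes for flag in sorted(o.flags))
        parts = ["no_valid_peaks"] + [f"{k}:{v}" for k, v in sorted(counts.items())]
        return PairResult(
            protein_id, metabolite_id, None, 0, (), ";".join(parts)
        )
    stat = {"mean": np.mean, "median": np.median, "max": np.max}[policy]
    by_rep: dict[int, list[float]] = defaultdict(list)
    for o in qualifying:
        by_rep[o.replicate].append(o.delta_rf)
    rep_values = tuple(float(stat(by_rep[r])) for r in sorted(by_rep))
    return PairResult(
        protein_id,
        metabolite_id,
        float(np.mean(rep_values)),
        len(qualifying),
        rep_values,
        "",
    )


# ----------------------------------------------------------------------


@dataclass
class InteractionMatrix:
    """Dense proteins x metabolites grid of aggregated ΔRF values.

    Missing cells (no qualifying peak) are NaN in ``delta_rf`` and carry a
    QC summary in ``qc``.  ``policy`` records the peak-aggregation rule used.
    """

    delta_rf: pd.DataFrame
    n_peaks: pd.DataFrame
    qc: dict = field(default_factory=dict)
    replicates: dict = field(default_factory=dict)
    policy: str = "mean"

    @property
    def proteins(self) -> list:
        return list(self.delta_rf.index)

    @property
    def metabolites(self) -> list:
        return list(self.delta_rf.columns)

    @property
    def n_pairs(self) -> int:
        return self.delta_rf.size

    def value(self, protein_id: str, metabolite_id: str) -> float | None:
        v = self.delta_rf.at[protein_id, metabolite_id]
        return None if pd.isna(v) else float(v)

    def evaluable_pairs(self) -> set:
        return {
            (p, m)
            for p in self.proteins
            for m in self.metabolites
            if not pd.isna(self.delta_rf.at[p, m])
        }

    def detections(self, cutoff: float) -> list:
        """Pairs with ΔRF strictly greater than the cutoff, sorted."""
        out = []
        for p in self.proteins:
            for m in self.metabolites:
                v = self.delta_rf.at[p, m]
                if not pd.isna(v) and v > cutoff:
                    out.append((p, m, float(v)))
        return out

    def marginals(self, cutoff: float) -> tuple[pd.Series, pd.Series]:
        """Interactions per protein and per metabolite at a cutoff."""
        det = self.delta_rf.gt(cutoff)
        return det.sum(axis=1), det.sum(axis=0)


def build_matrix(pair_results, proteins, metabolites) -> InteractionMatrix:
    """Assemble pair results into the dense matrix over the rosters.

    Cells without a submitted result are missing.  Duplicate submissions for
    one pair are an error.
    """
    proteins = list(proteins)
    metabolites = list(metabolites)
    dr = pd.DataFrame(np.nan, index=proteins, columns=metabolites, dtype=float)
    npk = pd.DataFrame(0, index=proteins, columns=metabolites, dtype=int)
    qc: dict = {}
    reps: dict = {}
    seen = set()
    policy = "mean"
    for r in pair_results:
        key = (r.protein_id, r.metabolite_id)
        if key in seen:
            raise ValueError(f"duplicate pair submission for {key}")
        seen.add(key)
        if r.protein_id not in dr.index or r.metabolite_id not in dr.columns:
            raise ValueError(f"pair {key} outside the rosters")
        if r.delta_rf is not None:
            dr.at[key] = r.delta_rf
        npk.at[key] = r.n_peaks_used
        if r.qc_flags:
            qc[key] = r.qc_flags
        if r.replicate_values:
            reps[key] = tuple(r.replicate_values)
    for p in proteins:
        for m in metabolites:
            if (p, m) not in seen:
                qc[(p, m)] = "no_valid_peaks"
    return InteractionMatrix(delta_rf=dr, n_peaks=npk, qc=qc, replicates=reps,
                             policy=policy)


# ----------------------------------------------------------------------
# Study-level quantification


def quantify_study(
    measurements,
    windows,
    thresholds: Thresholds = Thresholds(),
    policy: str = "mean",
    calibrate: bool = True,
    proteins=None,
    metabolites=None,
) -> tuple[InteractionMatrix, list[PeakQuant]]:
    """Run calibration, filtering and ΔRF quantification over a whole study.

    ``measurements`` is any iterable of M / P / PM sample measurements;
    ``windows`` the compiled peak windows (one list across all mixes).  M
    and PM spectra are paired strictly by (mix, long delay): a PM sample
    without a matching same-delay M reference is an error, never silently
    compared across delays.  Returns the interaction matrix and all
    peak-level quantifications for QC reporting.
    """
    if calibrate:
        measurements = [calibrate_measurement(m, thresholds) for m in measurements]
    m_index: dict = {}
    p_index: dict = {}
    pm_list = []
    for meas in measurements:
        if meas.role == "M":
            m_index[(meas.mix_id, meas.long_delay_ms)] = meas
        elif meas.role == "P":
            p_index[meas.protein_id] = meas
        else:
            pm_list.append(meas)

    windows_by_mix: dict = defaultdict(list)
    for w in windows:
        windows_by_mix[w.mix_id].append(w)

    rep_counter: Counter = Counter()
    outcomes: dict = defaultdict(list)
    quants: list[PeakQuant] = []
    for pm in pm_list:
        key_m = (pm.mix_id, pm.long_delay_ms)
        if key_m not in m_index:
            raise ValueError(
                f"no mix-only reference for mix {pm.mix_id!r} at "
                f"{pm.long_delay_ms:g} ms long delay (same-delay pairing required)"
            )
        if pm.protein_id not in p_index:
            raise ValueError(f"no protein-only reference for {pm.protein_id!r}")
        m_meas = m_index[key_m]
        p_meas = p_index[pm.protein_id]
        replicate = rep_counter[(pm.protein_id, pm.mix_id)]
        rep_counter[(pm.protein_id, pm.mix_id)] += 1
        for w in windows_by_mix.get(pm.mix_id, []):
            q = quantify_peak(m_meas, p_meas, pm, w, thresholds)
            quants.append(q)
            flags = set(q.flags)
            try:
                value = delta_rf(RelaxationQuadruple.from_quant(q))
            except UnevaluablePeak:
                value = None
                flags.add("unevaluable")
            outcomes[(pm.protein_id, w.metabolite_id)].append(
                PeakOutcome(value, frozenset(flags), replicate)
            )

    if proteins is None:
        proteins = sorted(p_index)
    if metabolites is None:
        metabolites = sorted({w.metabolite_id for w in windows})
    pair_results = [
        aggregate_pair(p, m, outs, policy) for (p, m), outs in sorted(outcomes.items())
    ]
    matrix = build_matrix(pair_results, proteins, metabolites)
    matrix.policy = policy
    return matrix, quants


# ----------------------------------------------------------------------
# Interaction-table I/O

_LONG_COLUMNS = (
    "protein_id",
    "metabolite_id",
    "delta_rf",
    "n_peaks_used",
    "qc_flags",
    "detected_at_cutoff",
    "replicate_values",
)


def write_interaction_table(
    matrix: InteractionMatrix,
    path: str | Path,
    wide_path: str | Path | None = None,
    cutoff: float | None = None,
) -> None:
    """Write the matrix as a long-format CSV (one row per pair) plus a wide
    proteins x metabolites CSV; values round-trip at full precision."""
    path = Path(path)
    if wide_path is None:
        wide_path = path.with_name(path.stem + "_wide" + path.suffix)
    rows = []
    for p in matrix.proteins:
        for m in matrix.metabolites:
            v = matrix.delta_rf.at[p, m]
            missing = pd.isna(v)
            detected = "" if cutoff is None else (not missing and v > cutoff)
            rows.append(
                {
                    "protein_id": p,
                    "metabolite_id": m,
                    "delta_rf": "" if missing else repr(float(v)),
                    "n_peaks_used": int(matrix.n_peaks.at[p, m]),
                    "qc_flags": matrix.qc.get((p, m), ""),
                    "detected_at_cutoff": detected,
                    "replicate_values": ";".join(
                        repr(x) for x in matrix.replicates.get((p, m), ())
                    ),
                }
            )
    pd.DataFrame(rows, columns=list(_LONG_COLUMNS)).to_csv(path, index=False)
    matrix.delta_rf.to_csv(wide_path, index_label="protein_id")


def read_interaction_table(path: str | Path) -> InteractionMatrix:
    """Read the long-format interaction CSV back into a matrix."""
    df = pd.read_csv(path, dtype={"qc_flags": str, "replicate_values": str})
    required = {"protein_id", "metabolite_id", "delta_rf"}
    if not required.issubset(df.columns):
        raise ValueError(f"interaction CSV must have columns {sorted(required)}")
    proteins = list(dict.fromkeys(df["protein_id"].astype(str)))
    metabolites = list(dict.fromkeys(df["metabolite_id"].astype(str)))
    results = []
    for r in df.itertuples(index=False):
        v = None if pd.isna(r.delta_rf) else float(r.delta_rf)
        qc = "" if pd.isna(getattr(r, "qc_flags", "")) else str(getattr(r, "qc_flags", ""))
        reps_raw = getattr(r, "replicate_values", "")
        reps = (
            tuple(float(x) for x in str(reps_raw).split(";"))
            if isinstance(reps_raw, str) and reps_raw
            else ()
        )
        if v is None and not qc:
            qc = "no_valid_peaks"
        results.append(
            PairResult(
                str(r.protein_id),
                str(r.metabolite_id),
                v,
                int(getattr(r, "n_peaks_used", 0) or 0),
                reps,
                qc,
            )
        )
    return build_matrix(results, proteins, metabolites)
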