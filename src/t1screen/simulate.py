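"""Synthetic screening studies with known binding ground truth.

The generator emulates the screen end to end: every metabolite peak is a
Lorentzian at its catalogued shift, the spin lock attenuates each peak by
exp(-R * t) with R the fast-exchange population average of the free and
bound relaxation rates, proteins contribute a broad baseline hump, a DSS
reference peak sits at 0 ppm, and nuisances (chemical-shift miscalibration,
additive noise, stagewise metabolite degradation) are applied on top.  The
result is a set of M / P / PM sample measurements in the same containers the
real pipeline consumes, plus an echo of the truth for scoring.

Everything is deterministic under the nuisance seed: the same seed yields
the same study byte for byte, and different seeds change only the noise and
offset draws, never the truth.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .binding import bound_fraction, observed_relaxation
from .spectra import SampleMeasurement, Spectrum1D
from .tables import MetabolitePeakList

STAGES = ("short_a", "long", "short_b")
_STAGE_EXPERIMENT = {
    "short_a": "t1rho_short_a",
    "long": "t1rho_long",
    "short_b": "t1rho_short_b",
}
# the long experiment accumulates twice the scans of each short replicate,
# so the summed short pair and the long spectrum share an intensity scale
LONG_SCAN_FACTOR = 2.0


@dataclass(frozen=True)
class AxisSpec:
    """Uniform descending ppm grid for rendered spectra."""

    ppm_min: float = -0.5
    ppm_max: float = 11.2
    step: float = 0.001

    def build(self) -> np.ndarray:
        n = int(round((self.ppm_max - self.ppm_min) / self.step)) + 1
        axis = self.ppm_max - self.step * np.arange(n)
        return np.round(axis, 9)


@dataclass(frozen=True)
class PeakSpec:
    """One rendered line: position, zero-delay amplitude, relaxation rate,
    and the per-stage fractional degradation loss of its parent compound."""

    ppm: float
    amplitude: float
    rate: float
    degradation: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be non-negative")
        if self.rate < 0:
            raise ValueError("relaxation rate must be non-negative")
        if not 0.0 <= self.degradation < 1.0:
            raise ValueError("degradation loss per stage must lie in [0, 1)")


@dataclass
class BindingTruth:
    """Ground-truth dissociation constants and relaxation rates.

    ``kd`` maps (protein_id, metabolite_id) to a KD in uM; absent pairs and
    ``math.inf`` both mean non-binder.  Concentrations default to the screen
    conditions of 15 uM protein monomer and 200 uM of each metabolite.  The
    default rates (r_free 1/s, r_bound 60/s) are chosen so that KDs in the
    10-500 uM range span the practically relevant ΔRF scale; they are
    configuration defaults, not physical claims about any real pair.
    """

    kd: dict = field(default_factory=dict)
    protein_conc: float = 15.0
    metabolite_conc: float = 200.0
    r_free: float = 1.0
    r_bound: float = 60.0

    def __post_init__(self) -> None:
        if self.protein_conc <= 0 or self.metabolite_conc <= 0:
            raise ValueError("concentrations must be positive")
        if not self.r_bound >= self.r_free > 0:
            raise ValueError("rates must satisfy r_bound >= r_free > 0")
        for key, v in self.kd.items():
            if not v > 0:
                raise ValueError(f"KD for {key} must be positive (got {v})")

    def kd_of(self, protein_id: str, metabolite_id: str) -> float:
        return self.kd.get((protein_id, metabolite_id), math.inf)

    def binders(self) -> set:
        return {k for k, v in self.kd.items() if math.isfinite(v)}

    def observed_rate(self, protein_id: str, metabolite_id: str) -> float:
        """Fast-exchange relaxation rate of the metabolite in this protein's
        presence (equals r_free for non-binders)."""
        pb = bound_fraction(
            self.protein_conc, self.metabolite_conc, self.kd_of(protein_id, metabolite_id)
        )
        return observed_relaxation(pb, self.r_free, self.r_bound)


@dataclass
class NuisanceModel:
    """Experimental imperfections layered onto the ideal spectra.

    noise_sd
        additive Gaussian noise per point, as a fraction of a unit peak.
    shift_offset_sd
        s.d. of the per-sample ppm miscalibration the DSS step must undo.
    degradation_rates
        metabolite_id -> fractional intensity loss per acquisition stage
        (short_a -> long -> short_b), emulating chemical instability.
    protein_baseline_amplitude
        height scale of the broad protein envelope in P and PM spectra.
    """

    noise_sd: float = 0.01
    shift_offset_sd: float = 0.004
    degradation_rates: dict = field(default_factory=dict)
    protein_baseline_amplitude: float = 0.3
    seed: int = 0
    dss_amplitude: float = 1.0
    dss_rate: float = 1.0
    protein_rate: float = 25.0
    linewidth: float = 0.004  # Lorentzian half width at half maximum, ppm
    tail_cutoff: float = 0.5  # render support half-width, ppm

    def __post_init__(self) -> None:
        for name in (
            "noise_sd",
            "shift_offset_sd",
            "protein_baseline_amplitude",
            "dss_amplitude",
            "dss_rate",
            "protein_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.linewidth <= 0 or self.tail_cutoff <= 0:
            raise ValueError("linewidth and tail_cutoff must be positive")
        for met, loss in self.degradation_rates.items():
            if not 0.0 <= loss < 1.0:
                raise ValueError(f"degradation loss for {met} must lie in [0, 1)")


# ----------------------------------------------------------------------
# Rendering


def _add_lorentzian(
    out: np.ndarray, axis: np.ndarray, center: float, amp: float, hwhm: float, cutoff: float
) -> None:
    # axis is descending; restrict to |ppm - center| <= cutoff so distant
    # peaks contribute exactly zero (numerical support truncation)
    i0 = int(np.searchsorted(-axis, -(center + cutoff)))
    i1 = int(np.searchsorted(-axis, -(center - cutoff), side="right"))
    x = axis[i0:i1]
    out[i0:i1] += amp * hwhm * hwhm / ((x - center) ** 2 + hwhm * hwhm)


def protein_baseline(protein_id: str, amplitude: float):
    """Deterministic broad envelope for a protein's own 1H signals.

    Returns a callable evaluating the envelope on a ppm array.  The hump
    layout is a stable function of the protein id, so the P and PM spectra
    of one protein share the identical envelope and the P-subtraction step
    downstream is exercised non-trivially.
    """
    rng = np.random.default_rng(zlib.crc32(protein_id.encode("utf-8")))
    centers = rng.uniform(0.8, 4.5, size=3)
    sigmas = rng.uniform(0.3, 0.8, size=3)
    amps = amplitude * rng.uniform(0.5, 1.0, size=3)

    def envelope(ppm: np.ndarray) -> np.ndarray:
        out = np.zeros_like(ppm, dtype=float)
        for c, s, a in zip(centers, sigmas, amps):
            out += a * np.exp(-0.5 * ((ppm - c) / s) ** 2)
        return out

    return envelope


def render_spectrum(
    peaks,
    spin_lock_ms: float,
    axis: AxisSpec | np.ndarray,
    nuisance: NuisanceModel,
    stage: str,
    *,
    rng: np.random.Generator | None = None,
    ppm_offset: float | None = None,
    scan_factor: float = 1.0,
    baseline=None,
    sample_id: str = "synthetic",
    role: str = "M",
    protein_id: str = "",
    mix_id: str = "",
) -> Spectrum1D:
    """Render one spin-lock spectrum from peak specifications.

    Each peak becomes a Lorentzian of height
    ``amplitude * exp(-rate * t) * (1 - degradation)**stage_index``, where
    ``t`` is the spin lock in seconds and the stage index counts acquisition
    order (short_a=0, long=1, short_b=2).  A DSS reference line (exempt from
    degradation) is always added at 0 ppm.  A global ppm offset (drawn from
    the nuisance model unless given) and additive Gaussian noise are applied
    last.  Deterministic for a given ``rng`` state.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    stage_index = STAGES.index(stage)
    ppm_axis = axis.build() if isinstance(axis, AxisSpec) else np.asarray(axis, dtype=float)
    lo, hi = float(ppm_axis.min()), float(ppm_axis.max())
    t = spin_lock_ms / 1000.0
    if rng is None:
        rng = np.random.default_rng(nuisance.seed)
    if ppm_offset is None:
        ppm_offset = (
            float(rng.normal(0.0, nuisance.shift_offset_sd))
            if nuisance.shift_offset_sd > 0
            else 0.0
        )

    specs = [p if isinstance(p, PeakSpec) else PeakSpec(*p) for p in peaks]
    intensity = np.zeros_like(ppm_axis)
    for p in specs:
        if not lo <= p.ppm <= hi:
            raise ValueError(f"peak at {p.ppm} ppm outside axis range [{lo}, {hi}]")
        height = (
            p.amplitude
            * math.exp(-p.rate * t)
            * (1.0 - p.degradation) ** stage_index
            * scan_factor
        )
        _add_lorentzian(
            intensity, ppm_axis, p.ppm + ppm_offset, height, nuisance.linewidth,
            nuisance.tail_cutoff,
        )
    # DSS reference at 0 ppm: exempt from degradation
    dss_height = nuisance.dss_amplitude * math.exp(-nuisance.dss_rate * t) * scan_factor
    _add_lorentzian(
        intensity, ppm_axis, ppm_offset, dss_height, nuisance.linewidth, nuisance.tail_cutoff
    )
    if baseline is not None:
        intensity += (
            baseline(ppm_axis - ppm_offset)
            * math.exp(-nuisance.protein_rate * t)
            * scan_factor
        )
    if nuisance.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, nuisance.noise_sd, size=ppm_axis.shape)

    return Spectrum1D(
        sample_id=sample_id,
        role=role,
        experiment=_STAGE_EXPERIMENT[stage],
        spin_lock_ms=spin_lock_ms,
        ppm=ppm_axis,
        intensity=intensity,
        protein_id=protein_id,
        mix_id=mix_id,
        meta={"true_ppm_offset": ppm_offset, "stage": stage},
    )


# ----------------------------------------------------------------------
# Whole-study generation


@dataclass
class StudyData:
    """A complete synthetic screen plus its ground truth."""

    measurements: list
    truth: BindingTruth
    nuisance: NuisanceModel
    peak_lists: dict
    mix_of: dict  # metabolite_id -> mix_id
    proteins: list
    metabolites: list
    small_proteins: frozenset = frozenset()

    def mixes(self) -> list:
        return sorted(set(self.mix_of.values()))

    def long_delay_for(self, protein_id: str) -> float:
        return 400.0 if protein_id in self.small_proteins else 200.0


def _measurement(
    sample_id: str,
    role: str,
    peaks: list,
    long_delay_ms: float,
    axis: np.ndarray,
    nuisance: NuisanceModel,
    rng: np.random.Generator,
    baseline=None,
    protein_id: str = "",
    mix_id: str = "",
) -> SampleMeasurement:
    offset = (
        float(rng.normal(0.0, nuisance.shift_offset_sd))
        if nuisance.shift_offset_sd > 0
        else 0.0
    )
    common = dict(
        axis=axis,
        nuisance=nuisance,
        rng=rng,
        ppm_offset=offset,
        baseline=baseline,
        sample_id=sample_id,
        role=role,
        protein_id=protein_id,
        mix_id=mix_id,
    )
    short_a = render_spectrum(peaks, 10.0, stage="short_a", scan_factor=1.0, **common)
    long = render_spectrum(
        peaks, long_delay_ms, stage="long", scan_factor=LONG_SCAN_FACTOR, **common
    )
    short_b = render_spectrum(peaks, 10.0, stage="short_b", scan_factor=1.0, **common)
    return SampleMeasurement(
        sample_id=sample_id,
        role=role,
        short_a=short_a,
        short_b=short_b,
        long=long,
        protein_id=protein_id,
        mix_id=mix_id,
        long_delay_ms=long_delay_ms,
    )


def generate_study(
    proteins: list,
    peak_lists: dict,
    mix_of: dict,
    truth: BindingTruth,
    nuisance: NuisanceModel,
    axis: AxisSpec = AxisSpec(),
    small_proteins=frozenset(),
) -> StudyData:
    """Generate the full measurement set of a screening study.

    Emits per mix one metabolite-only (M) measurement for every long delay
    required by the protein roster, one protein-only (P) measurement per
    protein, and one protein+mix (PM) measurement per (protein, mix) pair.
    Metabolite relaxation in PM samples follows the two-state fast-exchange
    model from the truth; proteins in ``small_proteins`` (below 40 kDa) use
    the 400 ms long delay, all others 200 ms.
    """
    metabolites = sorted(peak_lists)
    missing = [m for m in mix_of if m not in peak_lists]
    if missing:
        raise ValueError(f"mix assignment names metabolites without peak lists: {missing}")
    unassigned = [m for m in metabolites if m not in mix_of]
    if unassigned:
        raise ValueError(f"metabolites not assigned to any mix: {unassigned}")
    for (prot, met) in truth.kd:
        if prot not in proteins or met not in peak_lists:
            raise ValueError(f"truth entry {(prot, met)} outside the study rosters")
    small_proteins = frozenset(small_proteins)
    mixes = sorted(set(mix_of.values()))
    proteins = sorted(proteins)

    delays_needed: dict[str, set] = {mx: set() for mx in mixes}
    for prot in proteins:
        delay = 400.0 if prot in small_proteins else 200.0
        for mx in mixes:
            delays_needed[mx].add(delay)

    deg = nuisance.degradation_rates
    measurements = []
    counter = 0

    def next_rng() -> np.random.Generator:
        nonlocal counter
        counter += 1
        return np.random.default_rng([nuisance.seed, counter])

    # M: metabolite mix alone, free relaxation
    for mx in mixes:
        mets = sorted(m for m, assigned in mix_of.items() if assigned == mx)
        peaks = [
            PeakSpec(p, rel, truth.r_free, deg.get(met, 0.0))
            for met in mets
            for p, rel in peak_lists[met].peaks
        ]
        for delay in sorted(delays_needed[mx]):
            sid = f"M_{mx}_{int(delay)}ms"
            measurements.append(
                _measurement(sid, "M", peaks, delay, axis.build(), nuisance, next_rng(),
                             mix_id=mx)
            )

    # P: protein alone (baseline + DSS only)
    for prot in proteins:
        delay = 400.0 if prot in small_proteins else 200.0
        env = protein_baseline(prot, nuisance.protein_baseline_amplitude)
        sid = f"P_{prot}"
        measurements.append(
            _measurement(sid, "P", [], delay, axis.build(), nuisance, next_rng(),
                         baseline=env, protein_id=prot)
        )

    # PM: protein + mix, binding-enhanced relaxation per the truth
    for prot in proteins:
        delay = 400.0 if prot in small_proteins else 200.0
        env = protein_baseline(prot, nuisance.protein_baseline_amplitude)
        for mx in mixes:
            mets = sorted(m for m, assigned in mix_of.items() if assigned == mx)
            peaks = [
                PeakSpec(p, rel, truth.observed_rate(prot, met), deg.get(met, 0.0))
                for met in mets
                for p, rel in peak_lists[met].peaks
            ]
            sid = f"PM_{prot}_{mx}"
            measurements.append(
                _measurement(sid, "PM", peaks, delay, axis.build(), nuisance, next_rng(),
                             baseline=env, protein_id=prot, mix_id=mx)
            )

    return StudyData(
        measurements=measurements,
        truth=truth,
        nuisance=nuisance,
        peak_lists=dict(peak_lists),
        mix_of=dict(mix_of),
        proteins=list(proteins),
        metabolites=metabolites,
        small_proteins=small_proteins,
    )


def expected_delta_rf(truth: BindingTruth, kd: float, long_delay_ms: float = 200.0) -> float:
    """Closed-form ΔRF of a noiseless synthetic binder.

    With amplitude attenuation exp(-R t) and matched scan scales, the
    mix-alone ratio is exp(-r_free dt) and the protein-present ratio is
    exp(-r_obs dt) with dt the long/short spin-lock difference, so
    ΔRF = exp(-r_free dt) - exp(-r_obs dt).
    """
    dt = (long_delay_ms - 10.0) / 1000.0
    pb = bound_fraction(truth.protein_conc, truth.metabolite_conc, kd)
    r_obs = observed_relaxation(pb, truth.r_free, truth.r_bound)
    return math.exp(-truth.r_free * dt) - math.exp(-r_obs * dt)


# ----------------------------------------------------------------------
# Library and roster helpers


def synthetic_library(
    n_metabolites: int,
    seed: int = 0,
    mode: str = "territory",
    extra_peaks: tuple[int, int] = (0, 2),
    ppm_lo: float = 0.6,
    ppm_hi: float = 9.4,
    grid: float = 0.001,
) -> dict[str, MetabolitePeakList]:
    """Generate a synthetic metabolite peak-list library.

    ``territory`` mode gives every metabolite an anchor peak on an evenly
    spaced lattice and confines its extra peaks to its own neighbourhood, so
    any mix partition leaves every metabolite at least one clean window.
    ``scatter`` mode places extra peaks uniformly over the whole window so
    cross-metabolite clashes occur, exercising the mix designer.  All peak
    positions land on the rendering grid.
    """
    if n_metabolites < 1:
        raise ValueError("need at least one metabolite")
    if mode not in ("territory", "scatter"):
        raise ValueError("mode must be 'territory' or 'scatter'")
    rng = np.random.default_rng(seed)
    spacing = (ppm_hi - ppm_lo) / n_metabolites
    half = max(spacing / 2.0 - 0.03, 0.0)
    width = len(str(n_metabolites))
    out: dict[str, MetabolitePeakList] = {}
    for i in range(n_metabolites):
        met = f"met{i + 1:0{width}d}"
        anchor = round(round((ppm_lo + (i + 0.5) * spacing) / grid) * grid, 9)
        peaks = [(anchor, 1.0)]
        n_extra = int(rng.integers(extra_peaks[0], extra_peaks[1] + 1))
        for _ in range(n_extra):
            if mode == "territory" and half > 0.01:
                p = anchor + float(rng.uniform(-half, half))
            else:
                p = float(rng.uniform(ppm_lo, ppm_hi))
            p = round(round(p / grid) * grid, 9)
            rel = float(rng.uniform(0.3, 1.0))
            peaks.append((p, rel))
        out[met] = MetabolitePeakList(met, tuple(peaks))
    return out


def round_robin_mixes(metabolites, n_mixes: int) -> dict[str, str]:
    """Deterministic alternating assignment of metabolites to mixes."""
    if n_mixes < 1:
        raise ValueError("need at least one mix")
    return {
        met: f"mix{(i % n_mixes) + 1}" for i, met in enumerate(sorted(metabolites))
    }


def simulate_screen(
    n_proteins: int = 20,
    n_metabolites: int = 20,
    binder_fraction: float = 0.1,
    kd_range: tuple[float, float] = (10.0, 500.0),
    noise_sd: float = 0.01,
    seed: int = 0,
    n_mixes: int = 2,
    shift_offset_sd: float = 0.004,
    degradation_rates: dict | None = None,
    **truth_kwargs,
) -> StudyData:
    """One-call synthetic screen: library, mixes, truth, and all spectra.

    A fraction ``binder_fraction`` of the protein x metabolite grid is made
    to bind with KD drawn uniformly from ``kd_range`` (uM); everything else
    is a non-binder.  The binder set and KDs are a function of ``seed`` only.
    """
    rng = np.random.default_rng([seed, 971])
    proteins = [f"prot{i + 1:02d}" for i in range(n_proteins)]
    peak_lists = synthetic_library(n_metabolites, seed=seed)
    metabolites = sorted(peak_lists)
    mix_of = round_robin_mixes(metabolites, n_mixes)

    all_pairs = [(p, m) for p in proteins for m in metabolites]
    n_binders = int(round(binder_fraction * len(all_pairs)))
    idx = rng.choice(len(all_pairs), size=n_binders, replace=False)
    kd = {
        all_pairs[i]: float(rng.uniform(kd_range[0], kd_range[1]))
        for i in sorted(idx)
    }
    truth = BindingTruth(kd=kd, **truth_kwargs)
    nuisance = NuisanceModel(
        noise_sd=noise_sd,
        shift_offset_sd=shift_offset_sd,
        degradation_rates=degradation_rates or {},
        seed=seed,
    )
    return generate_study(proteins, peak_lists, mix_of, truth, nuisance)
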