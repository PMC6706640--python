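"""1D NMR spectra and sample measurements.

A screening sample comes in one of three roles: the metabolite mix alone
(``M``), the protein alone (``P``), or the protein-mix combination (``PM``).
Each sample is measured as a triple of spin-lock (T1rho) experiments: two
replicate short-delay spectra (10 ms spin lock) sandwiching one long-delay
spectrum (200 ms, or 400 ms for small proteins whose relaxation enhancement
is weaker).  Small molecules tumbling freely relax slowly during the spin
lock; molecules transiently bound to a large protein relax fast, so binders
lose intensity in the long-delay spectrum.

Spectra are stored on a descending ppm axis (NMR plotting convention) and
serialised to a plain two-column text format with a ``#key: value`` header.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

ROLES = ("M", "P", "PM")
EXPERIMENTS = (
    "t1rho_short_a",
    "t1rho_short_b",
    "t1rho_long",
    "t1rho_short_sum",
    "spin_echo",
)
SPIN_LOCK_DELAYS_MS = (10.0, 200.0, 400.0)

SHORT_DELAY_MS = 10.0
LONG_DELAYS_MS = (200.0, 400.0)


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file or constructor argument is malformed."""


@dataclass(eq=False)
class Spectrum1D:
    """A calibrated (or raw) 1D intensity trace on a ppm axis.

    The ppm axis is stored strictly descending; constructors re-sort input
    given in ascending order.  ``meta`` carries processing provenance such as
    the calibration shift and is never used in arithmetic.
    """

    sample_id: str
    role: str
    experiment: str
    spin_lock_ms: float
    ppm: np.ndarray
    intensity: np.ndarray
    protein_id: str = ""
    mix_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SpectrumFormatError(f"invalid role {self.role!r}, expected one of {ROLES}")
        if self.experiment not in EXPERIMENTS:
            raise SpectrumFormatError(
                f"invalid experiment {self.experiment!r}, expected one of {EXPERIMENTS}"
            )
        self.spin_lock_ms = float(self.spin_lock_ms)
        if self.spin_lock_ms not in SPIN_LOCK_DELAYS_MS:
            raise SpectrumFormatError(
                f"invalid spin lock delay {self.spin_lock_ms} ms, "
                f"expected one of {SPIN_LOCK_DELAYS_MS}"
            )
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumFormatError("ppm and intensity must be 1-D arrays")
        if len(self.ppm) != len(self.intensity):
            raise SpectrumFormatError(
                f"axis/intensity length mismatch: {len(self.ppm)} vs {len(self.intensity)}"
            )
        if len(self.ppm) < 2:
            raise SpectrumFormatError("spectrum needs at least two points")
        diffs = np.diff(self.ppm)
        if np.all(diffs > 0):  # ascending input: flip to NMR convention
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(diffs < 0):
            raise SpectrumFormatError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise SpectrumFormatError("intensities must all be finite")
        if not np.all(np.isfinite(self.ppm)):
            raise SpectrumFormatError("ppm axis must be finite")

    # ------------------------------------------------------------------
    def copy_with(self, **changes) -> "Spectrum1D":
        return replace(self, **changes)

    def window_slice(self, ppm_lo: float, ppm_hi: float) -> np.ndarray:
        """Intensities with ppm in the closed interval [ppm_lo, ppm_hi]."""
        if ppm_lo > ppm_hi:
            raise ValueError("ppm_lo must not exceed ppm_hi")
        if ppm_hi > self.ppm[0] or ppm_lo < self.ppm[-1]:
            raise ValueError(
                f"window [{ppm_lo}, {ppm_hi}] outside spectrum axis "
                f"[{self.ppm[-1]}, {self.ppm[0]}]"
            )
        mask = (self.ppm >= ppm_lo) & (self.ppm <= ppm_hi)
        return self.intensity[mask]

    def window_max(self, ppm_lo: float, ppm_hi: float) -> float:
        """Maximum intensity inside the closed ppm window (the quantification
        primitive used throughout the screen)."""
        vals = self.window_slice(ppm_lo, ppm_hi)
        if vals.size == 0:
            raise ValueError(f"window [{ppm_lo}, {ppm_hi}] contains no grid point")
        return float(vals.max())

    def same_axis(self, other: "Spectrum1D", atol: float = 1e-9) -> bool:
        return len(self.ppm) == len(other.ppm) and np.allclose(
            self.ppm, other.ppm, atol=atol, rtol=0.0
        )


@dataclass(eq=False)
class SampleMeasurement:
    """The (short_a, long, short_b) spin-lock triple for one sample.

    ``long_delay_ms`` is 200 ms by default and 400 ms for proteins below
    40 kDa, whose smaller relaxation enhancement needs a longer spin lock.
    """

    sample_id: str
    role: str
    short_a: Spectrum1D
    short_b: Spectrum1D
    long: Spectrum1D
    protein_id: str = ""
    mix_id: str = ""
    long_delay_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"invalid role {self.role!r}")
        if self.long_delay_ms not in LONG_DELAYS_MS:
            raise ValueError(f"long delay must be one of {LONG_DELAYS_MS} ms")
        for name, spec in (("short_a", self.short_a), ("short_b", self.short_b)):
            if spec.spin_lock_ms != SHORT_DELAY_MS:
                raise ValueError(f"{name} must use the {SHORT_DELAY_MS} ms spin lock")
        if self.long.spin_lock_ms != self.long_delay_ms:
            raise ValueError(
                f"long spectrum spin lock {self.long.spin_lock_ms} ms does not "
                f"match declared long delay {self.long_delay_ms} ms"
            )
        if self.role == "M" and self.protein_id:
            raise ValueError("mix-only (M) measurement must not carry a protein_id")
        if self.role == "P" and self.mix_id:
            raise ValueError("protein-only (P) measurement must not carry a mix_id")

    @property
    def spectra(self) -> tuple[Spectrum1D, Spectrum1D, Spectrum1D]:
        """Spectra in acquisition order short_a -> long -> short_b."""
        return (self.short_a, self.long, self.short_b)


# ----------------------------------------------------------------------
# File format: UTF-8 text, '#key: value' header lines, then TAB-separated
# 'ppm<TAB>intensity' rows.

_HEADER_FIELDS = ("sample_id", "role", "experiment", "spin_lock_ms")
_OPTIONAL_FIELDS = ("protein_id", "mix_id")


def read_spectrum(path: str | Path) -> Spectrum1D:
    """Read a spectrum from the two-column text format.

    The axis is re-sorted to descending order regardless of file row order.
    Malformed headers and non-numeric rows raise :class:`SpectrumFormatError`
    naming the offending line.
    """
    path = Path(path)
    header: dict[str, str] = {}
    ppm: list[float] = []
    intensity: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" not in body:
                    raise SpectrumFormatError(
                        f"{path}:{lineno}: header line without ':' separator"
                    )
                key, _, value = body.partition(":")
                header[key.strip()] = value.strip()
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) != 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                ppm.append(float(parts[0]))
                intensity.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}:{lineno}: non-numeric row") from exc
    for key in _HEADER_FIELDS:
        if key not in header:
            raise SpectrumFormatError(f"{path}: missing header field '{key}'")
    try:
        spin_lock = float(header["spin_lock_ms"])
    except ValueError as exc:
        raise SpectrumFormatError(f"{path}: non-numeric spin_lock_ms") from exc
    if spin_lock not in SPIN_LOCK_DELAYS_MS:
        raise SpectrumFormatError(f"{path}: invalid spin lock delay {spin_lock} ms")
    order = np.argsort(ppm)[::-1]
    arr_ppm = np.asarray(ppm)[order]
    arr_int = np.asarray(intensity)[order]
    return Spectrum1D(
        sample_id=header["sample_id"],
        role=header["role"],
        experiment=header["experiment"],
        spin_lock_ms=spin_lock,
        ppm=arr_ppm,
        intensity=arr_int,
        protein_id=header.get("protein_id", ""),
        mix_id=header.get("mix_id", ""),
    )


def write_spectrum(spec: Spectrum1D, path: str | Path) -> None:
    """Write a spectrum in the two-column text format (round-trips exactly)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#sample_id: {spec.sample_id}\n")
        fh.write(f"#role: {spec.role}\n")
        fh.write(f"#experiment: {spec.experiment}\n")
        fh.write(f"#spin_lock_ms: {spec.spin_lock_ms:g}\n")
        if spec.protein_id:
            fh.write(f"#protein_id: {spec.protein_id}\n")
        if spec.mix_id:
            fh.write(f"#mix_id: {spec.mix_id}\n")
        for x, y in zip(spec.ppm.tolist(), spec.intensity.tolist()):
            fh.write(f"{x!r}\t{y!r}\n")
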