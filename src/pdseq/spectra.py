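"""Spectrum I/O, preprocessing, and conversion to abstract mass coordinates.

Preprocessing follows three rules: peaks below a relative intensity floor are
removed, putative C13 isotope peaks are removed, and every surviving peak is
guaranteed a complementary partner (a peak whose mass sums with it to the
total mass M) by synthesising one where absent.  The synthetic flag is kept
on created peaks for diagnostics; downstream code treats them identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

from pyteomics import mgf as _mgf

from .chem import PROTON, WATER

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    mass: float
    intensity: float = 1.0
    synthetic: bool = False

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class Spectrum:
    """A sorted peak list plus the total (abstract, residue-sum) mass M."""

    peaks: tuple[Peak, ...]
    total_mass: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mass))
        )

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def masses(self) -> list[float]:
        return [p.mass for p in self.peaks]

    def replace_peaks(self, peaks: Sequence[Peak]) -> "Spectrum":
        return replace(self, peaks=tuple(peaks))


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters (all masses in Da).

    ``intensity_floor`` is relative to the maximum intensity; ``isotope_delta``
    is the C13-C12 spacing; ``merge_tol`` merges near-duplicate peaks;
    ``complement_tol`` decides whether a complementary partner already exists.
    """

    intensity_floor: float = 0.1
    isotope_delta: float = 1.00335
    merge_tol: float = 0.3
    complement_tol: float = 0.3
    #: create a synthetic partner for peaks lacking a complementary ion.
    #: On for experimental spectra; simulated spectra already carry the
    #: complete pair structure of their b/y ladder, so the simulation
    #: pipeline turns it off rather than mirror its own noise.
    complement_closure: bool = True


class SpectrumParseError(ValueError):
    pass


def read_mgf(path) -> list[Spectrum]:
    """Read an MGF file into raw spectra (peak m/z values left untouched).

    The total neutral peptide mass is computed as ``pepmass*z - z*proton`` and
    the abstract total mass (residue sum) as neutral mass minus water; both are
    stored in metadata, and ``total_mass`` is the abstract one.  Spectra with
    no PEPMASS are skipped with a warning.
    """
    spectra: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False) as reader:
        for block in reader:
            params = block.get("params", {})
            title = params.get("title", f"spectrum{len(spectra)}")
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                log.warning("skipping %r: missing PEPMASS", title)
                continue
            charge = params.get("charge")
            z = int(charge[0]) if charge else 1
            neutral = pepmass[0] * z - z * PROTON
            abstract_m = neutral - WATER
            peaks = tuple(
                Peak(float(m), float(i))
                for m, i in zip(block["m/z array"], block["intensity array"])
            )
            spectra.append(
                Spectrum(
                    peaks,
                    abstract_m,
                    {
                        "title": title,
                        "charge": z,
                        "pepmass": pepmass[0],
                        "neutral_mass": neutral,
                        "raw": True,
                    },
                )
            )
    return spectra


def read_peaklist(path, total_mass: float) -> Spectrum:
    """Read a two-column (mass, intensity) text file in abstract coordinates."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            try:
                mass = float(parts[0])
                intensity = float(parts[1]) if len(parts) > 1 else 1.0
            except (ValueError, IndexError) as exc:
                raise SpectrumParseError(
                    f"{path}:{lineno}: cannot parse peak line {line!r}"
                ) from exc
            peaks.append(Peak(mass, intensity))
    return Spectrum(tuple(peaks), total_mass, {"source": str(path)})


def write_peaklist(spectrum: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# total_mass {spectrum.total_mass:.5f}\n")
        for p in spectrum.peaks:
            fh.write(f"{p.mass:.5f}\t{p.intensity:.4f}\n")


def _merge_peaks(peaks: Sequence[Peak], tol: float) -> list[Peak]:
    """Merge peaks closer than ``tol``, keeping the most intense representative.

    A real (non-synthetic) peak wins over a synthetic one at equal intensity.
    """
    merged: list[Peak] = []
    for p in sorted(peaks, key=lambda q: q.mass):
        if merged and p.mass - merged[-1].mass <= tol:
            prev = merged[-1]
            better = max(
                (prev, p), key=lambda q: (q.intensity, not q.synthetic)
            )
            merged[-1] = better
        else:
            merged.append(p)
    return merged


def preprocess(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Intensity filter, isotope removal, dedup, and complement closure.

    Idempotent: applying it twice gives the same spectrum.  After it, every
    peak mass m has a partner m' with ``|m + m' - M| <= complement_tol``.
    """
    cfg = cfg or PreprocessConfig()
    M = s.total_mass
    if not s.peaks:
        return s
    peaks = [p for p in s.peaks if 0 < p.mass < M]
    if not peaks:
        return s.replace_peaks(())

    # (a) relative intensity floor
    imax = max(p.intensity for p in peaks)
    peaks = [p for p in peaks if p.intensity >= cfg.intensity_floor * imax]

    # (b) isotope removal: drop a peak one C13 spacing above a strictly more
    # intense peak
    kept: list[Peak] = []
    for p in peaks:
        is_isotope = any(
            abs(p.mass - q.mass - cfg.isotope_delta) <= cfg.merge_tol
            and q.intensity > p.intensity
            for q in peaks
        )
        if not is_isotope:
            kept.append(p)

    # (c) merge near-duplicates
    kept = _merge_peaks(kept, cfg.merge_tol)

    # (d) complement closure: add a synthetic partner at M - m where missing.
    # A peak within tolerance of M/2 is its own partner.
    if not cfg.complement_closure:
        return s.replace_peaks(kept)
    masses = [p.mass for p in kept]
    created: list[Peak] = []
    for p in kept:
        partner = M - p.mass
        if not 0 < partner < M:
            continue
        if any(abs(m - partner) <= cfg.complement_tol for m in masses):
            continue
        if any(abs(q.mass - partner) <= cfg.complement_tol for q in created):
            continue
        created.append(Peak(partner, p.intensity, synthetic=True))
    return s.replace_peaks(kept + created)


def calibrate_ions(s: Spectrum, charge: int | None = None) -> Spectrum:
    """Map raw singly-charged fragment m/z values into abstract coordinates.

    Each observed peak m yields two candidates: ``m - proton`` under the
    b-ion hypothesis and ``M - (m - proton - water)`` under the y-ion
    hypothesis.  Candidates outside (0, M) are dropped; near-duplicates are
    merged keeping the higher intensity.
    """
    M = s.total_mass
    candidates: list[Peak] = []
    for p in s.peaks:
        b = p.mass - PROTON
        y = M - (p.mass - PROTON - WATER)
        for cand in (b, y):
            if 0 < cand < M:
                candidates.append(Peak(cand, p.intensity))
    merged = _merge_peaks(candidates, 0.3)
    meta = dict(s.metadata)
    meta["raw"] = False
    return Spectrum(tuple(merged), M, meta)


def iter_input(path, mode: str, total_mass: float | None = None) -> Iterator[Spectrum]:
    """Yield abstract-coordinate spectra from an input file.

    ``mode='mgf'`` reads and ion-calibrates; ``mode='tsv'`` reads a peak list
    already in abstract coordinates (requires ``total_mass`` unless the file
    carries a ``# total_mass`` header line).
    """
    if mode == "mgf":
        for raw in read_mgf(path):
            yield calibrate_ions(raw)
    elif mode == "tsv":
        if total_mass is None:
            with open(path) as fh:
                first = fh.readline().split()
            if len(first) >= 3 and first[0] == "#" and first[1] == "total_mass":
                total_mass = float(first[2])
            else:
                raise SpectrumParseError(
                    "tsv input needs a total mass (flag or '# total_mass' header)"
                )
        yield read_peaklist(path, total_mass)
    else:
        raise ValueError(f"unknown input mode {mode!r}")
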