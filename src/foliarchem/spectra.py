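"""Fragmentation spectra: container, MGF round-trip, and cosine scoring.

A :class:`Spectrum` is a precursor m/z plus an m/z-sorted list of fragment
peaks.  Structural similarity between two spectra is scored as the cosine of
the angle between their matched fragment-intensity vectors: candidate peak
pairs within a fragment m/z tolerance (optionally also pairs offset by the
difference of the two precursor masses, the "modified cosine" used for
analog matching in molecular networks) are matched greedily by decreasing
intensity product, each peak used at most once, and the accepted dot product
is normalised by the full L2 norms of both spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .errors import InputError

__all__ = ["Spectrum", "cosine_score", "read_mgf", "write_mgf"]


@dataclass(frozen=True)
class Spectrum:
    """One fragmentation spectrum.

    Parameters
    ----------
    id : str
        Opaque identifier (MGF TITLE).
    precursor_mz : float
        Precursor ion m/z in Da; must be positive.
    mz : numpy.ndarray
        Fragment m/z values, strictly increasing.
    intensity : numpy.ndarray
        Fragment intensities, all positive, same length as ``mz``.
    """

    id: str
    precursor_mz: float
    mz: np.ndarray = field(repr=False)
    intensity: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.size == 0:
            raise InputError(f"spectrum {self.id!r}: peak list is empty")
        if mz.size != inten.size:
            raise InputError(f"spectrum {self.id!r}: mz/intensity length mismatch")
        if np.any(np.diff(mz) <= 0):
            raise InputError(f"spectrum {self.id!r}: fragment m/z not strictly increasing")
        if np.any(inten <= 0):
            raise InputError(f"spectrum {self.id!r}: non-positive intensity")
        if not self.precursor_mz > 0:
            raise InputError(f"spectrum {self.id!r}: precursor_mz must be > 0")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    @classmethod
    def from_peaks(cls, id: str, precursor_mz: float,
                   peaks: Iterable[tuple[float, float]]) -> "Spectrum":
        pk = sorted(peaks)
        mz = np.array([p[0] for p in pk], dtype=float)
        it = np.array([p[1] for p in pk], dtype=float)
        return cls(id=id, precursor_mz=precursor_mz, mz=mz, intensity=it)


def cosine_score(a: Spectrum, b: Spectrum, fragment_tol: float = 0.02,
                 intensity_power: float = 0.5,
                 allow_precursor_shift: bool = False) -> float:
    """Cosine similarity between two spectra over greedily matched peaks.

    Peaks ``i`` of ``a`` and ``j`` of ``b`` are candidate matches when
    ``|mz_a[i] - mz_b[j]| <= fragment_tol`` or, with ``allow_precursor_shift``,
    when the difference equals the precursor mass difference within the same
    tolerance.  Candidates are accepted in decreasing order of weighted
    intensity product with each peak used at most once; the score is the
    accepted dot product divided by the L2 norms of the full weighted
    intensity vectors, so it lies in [0, 1] and equals 1 only for identical
    spectra.  Intensities are raised to ``intensity_power`` before use.
    """
    if fragment_tol <= 0:
        raise InputError("fragment_tol must be > 0")
    wa = a.intensity ** intensity_power
    wb = b.intensity ** intensity_power
    norm = float(np.linalg.norm(wa) * np.linalg.norm(wb))
    if norm == 0.0:
        raise InputError("cannot score a spectrum with zero total intensity")

    dmz = a.mz[:, None] - b.mz[None, :]
    ok = np.abs(dmz) <= fragment_tol
    if allow_precursor_shift:
        shift = a.precursor_mz - b.precursor_mz
        ok |= np.abs(dmz - shift) <= fragment_tol
    ii, jj = np.nonzero(ok)
    if ii.size == 0:
        return 0.0
    prod = wa[ii] * wb[jj]
    order = np.argsort(-prod, kind="stable")
    used_a = np.zeros(a.n_peaks, dtype=bool)
    used_b = np.zeros(b.n_peaks, dtype=bool)
    dot = 0.0
    for k in order:
        i, j = ii[k], jj[k]
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = True
        used_b[j] = True
        dot += prod[k]
    return min(dot / norm, 1.0)


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    Tolerant of missing CHARGE; TITLE becomes the spectrum id (falling back
    to SCANS, then to a running index).
    """
    out: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for k, entry in enumerate(reader):
            params = entry["params"]
            sid = str(params.get("title", params.get("scans", k)))
            pepmass = params["pepmass"]
            prec = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            order = np.argsort(entry["m/z array"], kind="stable")
            out.append(Spectrum(id=sid, precursor_mz=prec,
                                mz=np.asarray(entry["m/z array"], float)[order],
                                intensity=np.asarray(entry["intensity array"], float)[order]))
    return out


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF, one BEGIN IONS block per spectrum.

    Peaks are written as ``mz intensity`` lines with fixed formatting so that
    identical inputs yield byte-identical files.
    """
    path = Path(path)
    with path.open("w") as fh:
        for k, sp in enumerate(spectra, start=1):
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.id}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.5f}\n")
            fh.write(f"SCANS={k}\n")
            for m, i in zip(sp.mz, sp.intensity):
                fh.write(f"{m:.5f} {i:.4f}\n")
            fh.write("END IONS\n")
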