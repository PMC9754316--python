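"""Molecular geometries: XYZ parsing/writing and nuclear-frame quantities.

Coordinates are stored in angstrom (the XYZ convention); conversion to bohr
happens only inside the integral routines.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_PER_ANGSTROM

# Elements the bundled STO-3G tables cover, with nuclear charges.
ELEMENT_Z = {"H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8}
Z_ELEMENT = {z: el for el, z in ELEMENT_Z.items()}


class XyzParseError(ValueError):
    """Raised for malformed XYZ input; the message names the offending line."""


@dataclass
class Geometry:
    """A molecule: element symbols, nuclear charges and positions in angstrom."""

    symbols: list[str]
    coords: np.ndarray  # (n_atoms, 3), angstrom
    net_charge: int = 0
    label: str = ""
    charges: np.ndarray = field(init=False)  # nuclear charges Z_m

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape != (len(self.symbols), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        unknown = [s for s in self.symbols if s not in ELEMENT_Z]
        if unknown:
            raise ValueError(f"unknown element(s): {unknown}")
        self.charges = np.array([ELEMENT_Z[s] for s in self.symbols], dtype=float)
        if self.n_electrons < 0:
            raise ValueError("negative electron count")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def n_electrons(self) -> int:
        return int(round(self.charges.sum())) - self.net_charge

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coords * BOHR_PER_ANGSTROM

    def translated(self, shift) -> "Geometry":
        return Geometry(list(self.symbols), self.coords + np.asarray(shift), self.net_charge, self.label)

    def rotated(self, rotation) -> "Geometry":
        rotation = np.asarray(rotation, dtype=float)
        return Geometry(list(self.symbols), self.coords @ rotation.T, self.net_charge, self.label)


def parse_xyz(text: str, label: str = "") -> Geometry:
    """Parse standard XYZ text (count line, comment, ``El x y z`` in angstrom).

    A net charge may be given in the comment line as ``charge=n``.
    """
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise XyzParseError("line 1: missing atom-count line")
    try:
        n_atoms = int(lines[0].strip())
    except ValueError as exc:
        raise XyzParseError(f"line 1: malformed atom count {lines[0].strip()!r}") from exc
    if len(lines) < 2 + n_atoms:
        raise XyzParseError(f"expected {n_atoms} atom lines, file has {max(0, len(lines) - 2)}")
    comment = lines[1] if len(lines) > 1 else ""
    match = re.search(r"charge\s*=\s*(-?\d+)", comment)
    net_charge = int(match.group(1)) if match else 0

    symbols: list[str] = []
    coords = np.empty((n_atoms, 3))
    for i in range(n_atoms):
        lineno = 3 + i
        parts = lines[2 + i].split()
        if len(parts) < 4:
            raise XyzParseError(f"line {lineno}: expected 'element x y z'")
        symbol = parts[0].capitalize()
        if symbol not in ELEMENT_Z:
            raise XyzParseError(f"line {lineno}: unknown element {parts[0]!r}")
        try:
            coords[i] = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise XyzParseError(f"line {lineno}: non-numeric coordinate") from exc
        symbols.append(symbol)
    return Geometry(symbols, coords, net_charge, label or comment.strip())


def write_xyz(geometry: Geometry) -> str:
    comment = geometry.label or "generated by pcmvqe"
    if geometry.net_charge != 0:
        comment = f"{comment} charge={geometry.net_charge}"
    lines = [str(geometry.n_atoms), comment]
    for sym, (x, y, z) in zip(geometry.symbols, geometry.coords):
        lines.append(f"{sym:<2s} {x: .10f} {y: .10f} {z: .10f}")
    return "\n".join(lines) + "\n"


def nuclear_repulsion(geometry: Geometry) -> float:
    """E_nn = sum_{m<n} Z_m Z_n / |R_m - R_n| in Hartree."""
    R = geometry.coords_bohr
    Z = geometry.charges
    e_nn = 0.0
    for m in range(geometry.n_atoms):
        for n in range(m + 1, geometry.n_atoms):
            r = np.linalg.norm(R[m] - R[n])
            if r < 1e-10:
                raise ValueError(f"coincident nuclei {m} and {n}")
            e_nn += Z[m] * Z[n] / r
    return e_nn


def nuclear_potential(geometry: Geometry, points: np.ndarray) -> np.ndarray:
    """Nuclear electrostatic potential v_N,i = sum_m Z_m / |R_m - s_i|.

    ``points`` are in bohr; a point coinciding with a nucleus is an error.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    dist = np.linalg.norm(points[:, None, :] - geometry.coords_bohr[None, :, :], axis=2)
    if np.any(dist < 1e-10):
        raise ZeroDivisionError("evaluation point coincides with a nucleus")
    return (geometry.charges[None, :] / dist).sum(axis=1)
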