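"""Desk-scale companions to all-atom simulations of the nanotube porin.

Charge bookkeeping for the carboxylate-functionalised nanotube model
(exact decimal arithmetic so paired ±0.115 e terminal contributions cancel
exactly) and ingestion of periodic-box centre-of-mass trajectories for the
diffusion analysis.  Running or parsing the simulations themselves is out
of scope; atom counts are supplied directly in the model spec.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CNTModelSpec",
    "ComTrajectory",
    "net_charge",
    "neutralizing_ion_excess",
    "read_com_csv",
    "write_com_csv",
]

ATOM_CLASSES = ("wall_C", "terminal_C", "terminal_H", "carboxyl_C", "carboxyl_O")

DEFAULT_CHARGES_E = {
    "wall_C": "0",
    "terminal_C": "-0.115",
    "terminal_H": "0.115",
    "carboxyl_C": "0.34",
    "carboxyl_O": "-0.67",
}


@dataclass
class CNTModelSpec:
    """Atom roster and partial charges of a carboxylate-terminated nanotube.

    Defaults describe a (14, 7) single-walled tube, 1.5 nm diameter and
    5.5 nm long, with 6 carboxylate groups per end (each contributing one
    carbon and two oxygens) and the remaining rim carbons hydrogen-
    terminated with equal and opposite ±0.115 e charges.
    """

    chiral_indices: tuple = (14, 7)
    length_nm: float = 5.5
    n_wall_carbons: int = 1008
    n_terminal_carbons: int = 30
    n_terminal_hydrogens: int = 30
    n_carboxylates_per_end: int = 6
    n_ends: int = 2
    charges: dict = field(default_factory=lambda: dict(DEFAULT_CHARGES_E))

    def __post_init__(self) -> None:
        for name in ("n_wall_carbons", "n_terminal_carbons",
                     "n_terminal_hydrogens", "n_carboxylates_per_end", "n_ends"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.charges) - set(ATOM_CLASSES)
        if unknown:
            raise ValueError(f"unknown atom class(es) in charges map: {sorted(unknown)}")
        missing = set(ATOM_CLASSES) - set(self.charges)
        if missing:
            raise ValueError(f"charges map missing atom class(es): {sorted(missing)}")

    def charge_e(self, atom_class: str) -> Decimal:
        return Decimal(str(self.charges[atom_class]))

    @property
    def n_carboxylates_total(self) -> int:
        return self.n_carboxylates_per_end * self.n_ends


def net_charge(spec: CNTModelSpec) -> Decimal:
    """Total charge of the model in units of e, by exact decimal summation.

    ``n_wall·q_wall + n_termC·q_termC + n_termH·q_termH
    + n_carboxylates·(q_carboxC + 2·q_carboxO)``; with the default charges
    each hydrogen-terminated rim pair cancels exactly and each carboxylate
    contributes 0.34 − 2·0.67 = −1 e.
    """
    total = (
        spec.n_wall_carbons * spec.charge_e("wall_C")
        + spec.n_terminal_carbons * spec.charge_e("terminal_C")
        + spec.n_terminal_hydrogens * spec.charge_e("terminal_H")
        + spec.n_carboxylates_total
        * (spec.charge_e("carboxyl_C") + 2 * spec.charge_e("carboxyl_O"))
    )
    return total


def neutralizing_ion_excess(spec: CNTModelSpec, cation_valence: int = 1,
                            anion_valence: int = -1) -> int:
    """Excess of cations over anions needed to neutralise the model's charge.

    For a net charge −q and monovalent salt this is simply q (e.g. −12 e
    requires 12 more cations than anions).  A non-integral requirement —
    net charge not divisible by the cation valence — raises ``ValueError``.
    """
    if cation_valence <= 0 or anion_valence >= 0:
        raise ValueError("cation_valence must be > 0 and anion_valence < 0")
    q = net_charge(spec)
    required = -q / Decimal(cation_valence)
    if required != required.to_integral_value():
        raise ValueError(
            f"net charge {q} e cannot be neutralised by integer counts of "
            f"valence-{cation_valence} cations"
        )
    return int(required)


@dataclass
class ComTrajectory:
    """Centre-of-mass time series from a periodic simulation box (nm, s)."""

    time_s: np.ndarray
    positions_nm: np.ndarray      # (n, 2) or (n, 3)
    box_nm: np.ndarray
    composition_label: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        self.box_nm = np.asarray(self.box_nm, dtype=float)
        if np.any(self.box_nm <= 0):
            raise ValueError("box lengths must be positive")
        dt = np.diff(self.time_s)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("timestamps must be uniformly spaced")
        if dt.size and dt[0] <= 0:
            raise ValueError("timestamps must be increasing")

    @property
    def frame_interval_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def xy_nm(self) -> np.ndarray:
        """In-plane coordinates (membrane-plane projection)."""
        return self.positions_nm[:, :2]


_HEADER_RE = re.compile(r"#\s*(\w+)\s*=\s*(.+)")

_UNIT_SCALE_TO_NM = {"nm": 1.0, "angstrom": 0.1, "a": 0.1, "Å": 0.1}


def read_com_csv(path: str | Path, composition_label: str = "") -> ComTrajectory:
    """Read a centre-of-mass CSV with ``# box_nm=...`` / ``# units=...`` headers.

    Expected layout: comment lines declaring the box lengths (nm) and the
    position units, then columns ``frame, time_s, x, y[, z]``.  Positions in
    Ångström are converted to nm.  Missing box or units declarations are an
    error — wrapped coordinates are meaningless without them.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    data_start = 0
    for i, line in enumerate(lines):
        m = _HEADER_RE.match(line.strip())
        if m:
            meta[m.group(1)] = m.group(2).strip()
            data_start = i + 1
        elif line.strip():
            break
    if "box_nm" not in meta:
        raise ValueError(f"{path.name}: missing '# box_nm=...' declaration")
    if "units" not in meta:
        raise ValueError(f"{path.name}: missing '# units=...' declaration")
    unit = meta["units"].lower()
    if unit not in _UNIT_SCALE_TO_NM:
        raise ValueError(f"{path.name}: unsupported units {meta['units']!r}")
    scale = _UNIT_SCALE_TO_NM[unit]
    box = np.array([float(v) for v in meta["box_nm"].split(",")])

    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[data_start:])))
    required = {"frame", "time_s", "x", "y"}
    if not required <= set(df.columns):
        raise ValueError(
            f"{path.name}: need columns {sorted(required)}; got {list(df.columns)}"
        )
    coord_cols = ["x", "y"] + (["z"] if "z" in df.columns else [])
    return ComTrajectory(
        time_s=df["time_s"].to_numpy(),
        positions_nm=df[coord_cols].to_numpy() * scale,
        box_nm=box[: len(coord_cols)],
        composition_label=composition_label or meta.get("composition", ""),
    )


def write_com_csv(traj: ComTrajectory, path: str | Path) -> None:
    """Write a centre-of-mass trajectory in the dialect read_com_csv expects."""
    path = Path(path)
    cols = ["x", "y", "z"][: traj.positions_nm.shape[1]]
    df = pd.DataFrame(traj.positions_nm, columns=cols)
    df.insert(0, "time_s", traj.time_s)
    df.insert(0, "frame", np.arange(len(df)))
    with path.open("w") as fh:
        fh.write("# box_nm=" + ",".join(f"{b:g}" for b in traj.box_nm) + "\n")
        fh.write("# units=nm\n")
        if traj.composition_label:
            fh.write(f"# composition={traj.composition_label}\n")
        df.to_csv(fh, index=False)
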