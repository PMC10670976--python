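"""Sigma-profile data model and text I/O.

A sigma profile is a histogram of a molecule's COSMO cavity surface area
over the screening charge density sigma (e/A^2).  It is the only molecular
descriptor the activity engine consumes.  Profiles live on a canonical
51-point lattice from -0.025 to +0.025 e/A^2 in steps of 0.001, the
convention used by the open sigma-profile databases, so that externally
computed profiles can be dropped in unchanged.

``p`` holds absolute surface area per bin (A^2), not a probability:
normalisation is the engine's job, and storing areas keeps the
"sum of bins equals total cavity area" invariant exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Optional, TextIO, Union

import numpy as np

__all__ = [
    "SIGMA_GRID",
    "SIGMA_STEP",
    "SigmaProfile",
    "ComponentRecord",
    "SigmaProfileError",
    "ProfileParseError",
    "read_sigma_profile",
    "write_sigma_profile",
    "regrid_profile",
]

#: canonical lattice of bin centers, e/A^2
SIGMA_STEP = 0.001
SIGMA_GRID = np.round(np.linspace(-0.025, 0.025, 51), 6)
SIGMA_GRID.setflags(write=False)


class SigmaProfileError(ValueError):
    """Invalid sigma-profile data."""


class ProfileParseError(SigmaProfileError):
    """Malformed sigma-profile text; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


def _uniform_step(grid: np.ndarray) -> float:
    d = np.diff(grid)
    if d.size == 0:
        raise SigmaProfileError("grid needs at least two points")
    if not np.allclose(d, d[0], rtol=0, atol=1e-9):
        raise SigmaProfileError("grid is not uniform")
    return float(d[0])


@dataclass(frozen=True)
class SigmaProfile:
    """Per-molecule surface-charge-density histogram.

    Parameters
    ----------
    name : str
        Identifier of the molecule.
    area : float
        Total cavity surface area, A^2.  Must equal ``p.sum()``.
    volume : float
        Cavity volume, A^3.
    p : ndarray, shape (51,)
        Surface area per bin, A^2, on :data:`SIGMA_GRID`.
    p_hb : ndarray or None
        Optional hydrogen-bonding sub-profile (area of bins belonging to
        hb-capable surface patches); ``0 <= p_hb <= p`` bin-wise.
    """

    name: str
    area: float
    volume: float
    p: np.ndarray
    p_hb: Optional[np.ndarray] = None
    grid: np.ndarray = field(default_factory=lambda: SIGMA_GRID)

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "grid", grid)
        if p.shape != grid.shape:
            raise SigmaProfileError(
                f"{self.name}: p has {p.size} bins but grid has {grid.size}"
            )
        if grid.shape == SIGMA_GRID.shape and not np.allclose(
            grid, SIGMA_GRID, atol=1e-9
        ):
            _uniform_step(grid)  # non-canonical grids allowed pre-regrid
        if np.any(p < 0):
            raise SigmaProfileError(f"{self.name}: negative bin area")
        total = float(p.sum())
        if self.area > 0 and not np.isclose(total, self.area, rtol=1e-6, atol=1e-9):
            raise SigmaProfileError(
                f"{self.name}: sum(p)={total:.6g} != area={self.area:.6g}"
            )
        if self.p_hb is not None:
            p_hb = np.asarray(self.p_hb, dtype=float)
            object.__setattr__(self, "p_hb", p_hb)
            if p_hb.shape != p.shape:
                raise SigmaProfileError(f"{self.name}: hb sub-profile shape mismatch")
            if np.any(p_hb < -1e-12) or np.any(p_hb > p + 1e-9):
                raise SigmaProfileError(f"{self.name}: hb sub-profile outside [0, p]")
        if self.volume < 0:
            raise SigmaProfileError(f"{self.name}: negative volume")

    @property
    def normalized(self) -> np.ndarray:
        """p / area — the probability profile the engine mixes."""
        if self.area <= 0:
            raise SigmaProfileError(f"{self.name}: zero-area profile")
        return self.p / self.area

    def polar_fraction(self, cutoff: float = 0.01) -> float:
        """Fraction of surface at |sigma| > cutoff (default 0.01 e/A^2)."""
        if self.area <= 0:
            return 0.0
        mask = np.abs(self.grid) > cutoff + 1e-12
        return float(self.p[mask].sum() / self.area)

    def with_name(self, name: str) -> "SigmaProfile":
        return replace(self, name=name)


@dataclass(frozen=True)
class ComponentRecord:
    """Registry entry tying a species to its bulk properties and profile.

    ``liquid_molar_volume`` (cm^3/mol) feeds the phase-volume quotient of
    the partition-ratio relation; for solids it is a hypothetical subcooled
    liquid value and ``density`` is then left unset.
    """

    name: str
    molar_mass: float  # g/mol
    liquid_molar_volume: float  # cm^3/mol
    density: Optional[float] = None  # g/cm^3
    sigma_profile: Optional[SigmaProfile] = None

    def __post_init__(self):
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar_mass must be positive")
        if self.liquid_molar_volume <= 0:
            raise ValueError(f"{self.name}: liquid_molar_volume must be positive")
        if self.density is not None:
            implied = self.density * self.liquid_molar_volume
            if abs(implied - self.molar_mass) / self.molar_mass > 0.02:
                raise ValueError(
                    f"{self.name}: density*volume={implied:.2f} g/mol deviates "
                    f">2% from molar_mass={self.molar_mass:.2f}"
                )

    def require_profile(self) -> SigmaProfile:
        if self.sigma_profile is None:
            raise ValueError(f"{self.name}: no sigma profile attached")
        return self.sigma_profile


# ---------------------------------------------------------------------------
# text I/O
#
# Dialects:
#   "vt2005"  — two columns: sigma  p(sigma)
#   "hb"      — three columns: sigma  p(sigma)  p_hb(sigma)
# Comment lines start with '#'; '# key: value' headers carry name/area/volume.


def write_sigma_profile(
    profile: SigmaProfile, stream: Union[TextIO, None] = None, dialect: str = "vt2005"
) -> str:
    """Serialize a profile; returns the text (also written to `stream`)."""
    if dialect not in ("vt2005", "hb"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "hb" and profile.p_hb is None:
        raise SigmaProfileError(f"{profile.name}: no hb split to write")
    lines = [
        f"# name: {profile.name}",
        f"# area: {float(profile.area)!r}",
        f"# volume: {float(profile.volume)!r}",
    ]
    for i, (s, pv) in enumerate(zip(profile.grid, profile.p)):
        if dialect == "hb":
            lines.append(f"{s: .6f} {float(pv)!r} {float(profile.p_hb[i])!r}")
        else:
            lines.append(f"{s: .6f} {float(pv)!r}")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text


def read_sigma_profile(
    source: Union[str, TextIO], dialect: str = "auto"
) -> SigmaProfile:
    """Parse a sigma-profile text stream.

    Accepts the canonical 51-bin lattice directly; any other uniform grid is
    conservatively rebinned onto it (total area preserved).
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    name, area, volume = "unnamed", None, 0.0
    sigmas, ps, phbs = [], [], []
    ncols = None
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip().lower()
                val = val.strip()
                if key == "name":
                    name = val
                elif key in ("area", "volume"):
                    try:
                        num = float(val)
                    except ValueError:
                        raise ProfileParseError(f"bad {key} header {val!r}", lineno)
                    if key == "area":
                        area = num
                    else:
                        volume = num
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise ProfileParseError(f"expected 2 or 3 columns, got {len(parts)}", lineno)
        if ncols is None:
            ncols = len(parts)
        elif len(parts) != ncols:
            raise ProfileParseError("inconsistent column count", lineno)
        try:
            vals = [float(v) for v in parts]
        except ValueError:
            raise ProfileParseError(f"non-numeric row {line!r}", lineno)
        sigmas.append(vals[0])
        ps.append(vals[1])
        if len(vals) == 3:
            phbs.append(vals[2])
    if not sigmas:
        raise ProfileParseError("no data rows")
    if dialect == "vt2005" and ncols != 2:
        raise ProfileParseError("vt2005 dialect expects 2 columns")
    if dialect == "hb" and ncols != 3:
        raise ProfileParseError("hb dialect expects 3 columns")
    grid = np.asarray(sigmas)
    p = np.asarray(ps)
    if np.any(p < 0):
        bad = int(np.argmax(p < 0)) + 1
        raise SigmaProfileError(f"negative p at data row {bad}")
    p_hb = np.asarray(phbs) if phbs else None
    total = float(p.sum())
    prof = SigmaProfile(
        name=name,
        area=area if area is not None else total,
        volume=volume,
        p=p,
        p_hb=p_hb,
        grid=grid,
    )
    if prof.grid.shape != SIGMA_GRID.shape or not np.allclose(
        prof.grid, SIGMA_GRID, atol=1e-9
    ):
        prof = regrid_profile(prof, SIGMA_GRID)
    return prof


def regrid_profile(profile: SigmaProfile, target_grid: np.ndarray) -> SigmaProfile:
    """Conservative rebinning onto a uniform target grid.

    Each source bin is a box of width equal to the source step centered on
    its grid point; its area is distributed over target bins in proportion
    to geometric overlap.  Total area is conserved to round-off and
    non-negativity is preserved.  Mass falling outside the target range is
    accumulated into the edge bins (clamped) so nothing is lost.
    """
    src_grid = np.asarray(profile.grid, dtype=float)
    tgt_grid = np.asarray(target_grid, dtype=float)
    hs = _uniform_step(src_grid) / 2.0
    ht = _uniform_step(tgt_grid) / 2.0
    out = np.zeros_like(tgt_grid)
    out_hb = np.zeros_like(tgt_grid) if profile.p_hb is not None else None
    tlo = tgt_grid - ht
    thi = tgt_grid + ht
    for c, mass, i in zip(src_grid, profile.p, range(src_grid.size)):
        if mass == 0 and (out_hb is None or profile.p_hb[i] == 0):
            continue
        lo, hi = c - hs, c + hs
        overlap = np.clip(np.minimum(hi, thi) - np.maximum(lo, tlo), 0.0, None)
        w = overlap.sum()
        if w <= 0:  # entirely outside: clamp to nearest edge bin
            j = 0 if c < tgt_grid[0] else tgt_grid.size - 1
            out[j] += mass
            if out_hb is not None:
                out_hb[j] += profile.p_hb[i]
            continue
        frac = overlap / w
        out += mass * frac
        if out_hb is not None:
            out_hb += profile.p_hb[i] * frac
    return SigmaProfile(
        name=profile.name,
        area=float(out.sum()),
        volume=profile.volume,
        p=out,
        p_hb=out_hb,
        grid=np.round(tgt_grid, 9),
    )
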