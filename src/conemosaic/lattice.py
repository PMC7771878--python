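"""Anisotropic triangular lattice geometry of the UV-cone sublattice.

Conventions
-----------
Rows radiate from the retinal center; columns run circumferentially,
parallel to the growing rim.  Measured UV-cone spacings in adult zebrafish
are roughly 10.25 um between neighbors within a row (``a_row``) and
12.25 um between neighbors within a column (``a_col``), so the
column-to-row spacing ratio is about 6/5 instead of the sqrt(3) of an
isotropic triangular lattice.

On the flattened retina we use Cartesian coordinates ``(x, y)`` in um; for
frustum samples these are obtained by unrolling the cone, which is
isometric to the plane.  The lattice bonds of a cone are two row bonds of
length ``a_row`` and four oblique bonds of length
``sqrt((a_row/2)**2 + (a_col/2)**2)``; the column direction is *not* a
principal lattice direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class LatticeSpec:
    """Spacings of the anisotropic triangular UV-cone lattice (um).

    Parameters
    ----------
    a_row
        Spacing between adjacent UV cones within one row.
    a_col
        Spacing between UV cones within one column.

    Derived quantities
    ------------------
    inter_row
        Circumferential spacing between adjacent rows, ``a_col / 2``.
    ring_spacing
        Radial spacing between successive circumferential rings of UV
        cones, ``a_row / 2`` (cones of adjacent rows sit on alternating
        rings).
    oblique
        Nearest-neighbor bond length between cones of adjacent rows.
    ratio
        Anisotropy ratio ``a_col / a_row`` (sqrt(3) when isotropic).
    pfc_stretch
        Stretch factor ``b = sqrt(sqrt(3) * a_row / a_col)`` that makes the
        one-mode phase-field-crystal lattice reproduce ``ratio``.
    """

    a_row: float
    a_col: float
    inter_row: float = field(init=False)
    ring_spacing: float = field(init=False)
    oblique: float = field(init=False)
    ratio: float = field(init=False)
    pfc_stretch: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.a_row > 0 and self.a_col > 0):
            raise ValueError(
                f"lattice spacings must be positive, got a_row={self.a_row}, "
                f"a_col={self.a_col}"
            )
        object.__setattr__(self, "inter_row", self.a_col / 2.0)
        object.__setattr__(self, "ring_spacing", self.a_row / 2.0)
        object.__setattr__(
            self,
            "oblique",
            math.hypot(self.a_row / 2.0, self.a_col / 2.0),
        )
        object.__setattr__(self, "ratio", self.a_col / self.a_row)
        object.__setattr__(
            self,
            "pfc_stretch",
            math.sqrt(math.sqrt(3.0) * self.a_row / self.a_col),
        )

    def to_dict(self) -> dict:
        return {"a_row": self.a_row, "a_col": self.a_col}


def make_lattice_spec(a_row: float = 10.25, a_col: float = 12.25) -> LatticeSpec:
    """Build a :class:`LatticeSpec`; defaults are the measured adult spacings."""
    return LatticeSpec(float(a_row), float(a_col))


@dataclass(frozen=True)
class FrustumGeometry:
    """Flattened cone frustum on which the mosaic grows.

    A cone frustum unrolls isometrically into an annular sector of opening
    angle ``sector_angle`` (rad).  Points are described by slant radius
    ``s`` (distance from the apex, um) and sector angle ``phi`` in
    ``[0, sector_angle)``; angular positions are periodic at the sector
    edges.  The circumference at slant ``s`` is ``C(s) = sector_angle * s``.

    With one circumferential ring of UV cones per ``ring_spacing`` of added
    slant, the expected number of row insertions per added ring is
    ``sector_angle * ring_spacing / inter_row``; the opening angle
    ``2 * a_col / a_row`` makes that rate exactly two, matching the defect
    density of the retina.

    Parameters
    ----------
    sector_angle
        Opening angle of the flattened sector, rad (0..2*pi].
    s_top
        Slant radius of the innermost ring, um.
    n_initial_rows
        Number of rows at the innermost ring.
    n_columns
        Number of rings added during growth.
    """

    sector_angle: float
    s_top: float
    n_initial_rows: int
    n_columns: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.sector_angle <= 2.0 * math.pi + 1e-12):
            raise ValueError("sector_angle must lie in [0, 2*pi]")
        if self.n_initial_rows < 3:
            raise ValueError("need at least 3 initial rows")
        if self.s_top <= 0:
            raise ValueError("s_top must be positive")
        if self.n_columns < 0:
            raise ValueError("n_columns must be non-negative")

    def circumference(self, s: float) -> float:
        return self.sector_angle * s

    def insertion_rate(self, spec: LatticeSpec) -> float:
        """Expected row insertions per added ring."""
        return self.sector_angle * spec.ring_spacing / spec.inter_row

    def to_dict(self) -> dict:
        return {
            "sector_angle": self.sector_angle,
            "s_top": self.s_top,
            "n_initial_rows": self.n_initial_rows,
            "n_columns": self.n_columns,
        }


def frustum_for_rows(
    spec: LatticeSpec,
    n_initial_rows: int,
    n_columns: int,
    sector_angle: float | None = None,
) -> FrustumGeometry:
    """Frustum whose innermost circumference carries ``n_initial_rows`` rows.

    When ``sector_angle`` is omitted, the canonical opening angle
    ``2 * a_col / a_row`` (two insertions per added ring) is used.  For a
    cylinder-like geometry pass ``sector_angle=0``; then ``s_top`` is taken
    as the matching circumference over an arbitrarily small angle and the
    row count never changes.
    """
    if sector_angle is None:
        sector_angle = 2.0 * spec.a_col / spec.a_row
    target_circ = n_initial_rows * spec.inter_row
    if sector_angle == 0.0:
        # Degenerate cylinder: keep s_top finite by storing the circumference
        # directly; callers treat sector_angle == 0 specially.
        return FrustumGeometry(0.0, target_circ, n_initial_rows, n_columns)
    s_top = target_circ / sector_angle
    return FrustumGeometry(sector_angle, s_top, n_initial_rows, n_columns)
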