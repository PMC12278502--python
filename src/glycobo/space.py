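"""Constrained mixed discrete/continuous glycosylation condition space.

The search domain couples ten directly controlled condition parameters —
donor anomeric configuration, lithium salt identity and loading, acid
catalyst, acceptor equivalents, concentration, two solvent fractions,
molecular sieves, and temperature — under one linear constraint: the Et2O
and MeCN fractions of the ternary solvent system must sum to at most 1,
the balance being DCM (an eleventh, derived parameter).

Categorical reagents carry registered integer codes (acids ordered by
acidity, sieves by pore size, salts by a PCA-derived rank) so that a single
numeric vector can feed a Gaussian-process surrogate; :func:`encode` and
:func:`decode` realize that mapping and are exact inverses on valid
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ParameterSpec",
    "ReactionSpace",
    "Conditions",
    "build_default_space",
    "validate_conditions",
    "sample_random",
    "encode",
    "decode",
]

#: canonical labels
DONOR_CONFIGS = ("alpha", "beta")
SALTS = ("LiI", "LiBF4", "LiClO4", "LiOTf", "LiNTf2", "LiPF6", "LiB(C6F5)4")
ACIDS = ("None", "Acetic", "Formic", "Oxalic", "TFA")
SIEVES = ("None", "3A", "4A", "5A")
TEMPERATURES = (0, 25)

#: default ordinal codes. Acids ascend in acidity (pKa 4.76, 3.75, 1.25,
#: 0.23) with "None" reserved at 0; sieves ascend in pore size; donor
#: configuration is alpha=0, beta=1 by convention.
ACID_CODES = {"None": 0, "Acetic": 1, "Formic": 2, "Oxalic": 3, "TFA": 4}
SIEVE_CODES = {"None": 0, "3A": 1, "4A": 2, "5A": 3}
DONOR_CODES = {"alpha": 0, "beta": 1}

#: fallback salt ranks used when no descriptor table is supplied; matches
#: the bundled descriptor table's first-principal-component ranking.
DEFAULT_SALT_CODES = {
    "LiI": 1,
    "LiBF4": 2,
    "LiClO4": 3,
    "LiOTf": 4,
    "LiNTf2": 5,
    "LiPF6": 6,
    "LiB(C6F5)4": 7,
}

_KINDS = ("binary", "ordinal-integer", "continuous", "discrete-set")


@dataclass(frozen=True)
class ParameterSpec:
    """One dimension of the reaction space.

    ``levels`` (with parallel integer ``codes``) describe discrete
    parameters; ``bounds`` in native units describe continuous ones.
    """

    name: str
    kind: str
    levels: tuple = ()
    codes: tuple = ()
    bounds: tuple = ()
    units: str = ""

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "continuous":
            lo, hi = self.bounds
            if not lo < hi:
                raise ValueError(f"{self.name}: bounds must satisfy low < high")
        else:
            if len(set(self.levels)) != len(self.levels) or not self.levels:
                raise ValueError(f"{self.name}: levels must be distinct and non-empty")
            if self.kind == "binary" and len(self.levels) != 2:
                raise ValueError(f"{self.name}: binary parameter needs exactly 2 levels")
            if len(self.codes) != len(self.levels):
                raise ValueError(f"{self.name}: one code per level required")
            if list(self.codes) != sorted(self.codes):
                raise ValueError(f"{self.name}: codes must be ascending")

    @property
    def is_continuous(self) -> bool:
        return self.kind == "continuous"

    def code_of(self, label) -> int:
        return self.codes[self.levels.index(label)]

    def label_of(self, code):
        return self.levels[self.codes.index(code)]


@dataclass(frozen=True)
class Conditions:
    """One concrete assignment of all ten direct condition parameters."""

    donor_config: str
    li_salt: str
    li_salt_eq: float
    acid: str
    acceptor_eq: float
    conc: float
    part_et2o: float
    part_mecn: float
    sieves: str
    temp: int

    @property
    def part_dcm(self) -> float:
        """Derived DCM fraction of the ternary solvent system."""
        return 1.0 - self.part_et2o - self.part_mecn

    def as_dict(self) -> dict:
        return {
            "donor_config": self.donor_config,
            "li_salt": self.li_salt,
            "li_salt_eq": self.li_salt_eq,
            "acid": self.acid,
            "acceptor_eq": self.acceptor_eq,
            "conc": self.conc,
            "part_et2o": self.part_et2o,
            "part_mecn": self.part_mecn,
            "sieves": self.sieves,
            "temp": self.temp,
        }

    def with_value(self, name: str, value) -> "Conditions":
        return replace(self, **{name: value})


@dataclass(frozen=True)
class ReactionSpace:
    """Ordered parameter specs plus the solvent-fraction constraint.

    The constraint is fixed by construction: ``part_et2o + part_mecn <= 1``
    (the derived DCM fraction must be non-negative).
    """

    parameters: tuple

    def __post_init__(self):
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")

    @property
    def names(self) -> tuple:
        return tuple(p.name for p in self.parameters)

    def spec(self, name: str) -> ParameterSpec:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(f"no parameter named {name!r}")

    @property
    def dim(self) -> int:
        return len(self.parameters)

    def axis_range(self, p: ParameterSpec) -> tuple:
        """Numeric range of a parameter's encoded axis (code or native range)."""
        if p.is_continuous:
            return (0.0, 1.0)
        return (float(min(p.codes)), float(max(p.codes)))


def build_default_space(salt_codes: Mapping[str, int] | None = None) -> ReactionSpace:
    """The ten-direct-parameter glycosylation space (11 with derived DCM).

    Continuous bounds envelope the campaign data with small margins:
    salt loading 0.5-5.0 eq, acceptor 0.8-3.0 eq, concentration
    0.03-0.31 M, solvent fractions on [0, 1].

    Parameters
    ----------
    salt_codes
        Optional salt -> integer map (e.g. from
        :func:`glycobo.descriptors.pca_rank_encode`); defaults to the
        bundled PCA ranking.
    """
    sc = dict(DEFAULT_SALT_CODES if salt_codes is None else salt_codes)
    salt_levels = tuple(sorted(SALTS, key=lambda s: sc[s]))
    salt_code_tuple = tuple(sc[s] for s in salt_levels)
    params = (
        ParameterSpec("donor_config", "binary", DONOR_CONFIGS,
                      tuple(DONOR_CODES[x] for x in DONOR_CONFIGS)),
        ParameterSpec("li_salt", "ordinal-integer", salt_levels, salt_code_tuple),
        ParameterSpec("li_salt_eq", "continuous", bounds=(0.5, 5.0), units="equivalents"),
        ParameterSpec("acid", "ordinal-integer", ACIDS,
                      tuple(ACID_CODES[x] for x in ACIDS)),
        ParameterSpec("acceptor_eq", "continuous", bounds=(0.8, 3.0), units="equivalents"),
        ParameterSpec("conc", "continuous", bounds=(0.03, 0.31), units="mol/L"),
        ParameterSpec("part_et2o", "continuous", bounds=(0.0, 1.0), units="fraction"),
        ParameterSpec("part_mecn", "continuous", bounds=(0.0, 1.0), units="fraction"),
        ParameterSpec("sieves", "ordinal-integer", SIEVES,
                      tuple(SIEVE_CODES[x] for x in SIEVES)),
        ParameterSpec("temp", "discrete-set", TEMPERATURES, TEMPERATURES, units="degC"),
    )
    return ReactionSpace(params)


_CONSTRAINT_TOL = 1e-9


def validate_conditions(space: ReactionSpace, c: Conditions) -> list[str]:
    """Return a list of violations; empty list means the conditions are valid.

    Unknown labels and out-of-bound values are reported as named
    violations rather than raised.
    """
    violations: list[str] = []
    d = c.as_dict()
    for p in space.parameters:
        v = d[p.name]
        if p.is_continuous:
            try:
                x = float(v)
            except (TypeError, ValueError):
                violations.append(f"{p.name}: non-numeric value {v!r}")
                continue
            lo, hi = p.bounds
            if not (lo - _CONSTRAINT_TOL <= x <= hi + _CONSTRAINT_TOL):
                violations.append(f"{p.name}: {x} outside bounds [{lo}, {hi}]")
        else:
            if v not in p.levels:
                violations.append(f"{p.name}: unknown label {v!r}")
    if c.part_et2o + c.part_mecn > 1.0 + _CONSTRAINT_TOL:
        violations.append(
            f"part_et2o+part_mecn: {c.part_et2o + c.part_mecn:.4f} exceeds 1 "
            "(derived DCM fraction would be negative)"
        )
    return violations


def is_valid(space: ReactionSpace, c: Conditions) -> bool:
    return not validate_conditions(space, c)


def sample_random(space: ReactionSpace, n: int, rng: np.random.Generator) -> list[Conditions]:
    """Draw ``n`` valid conditions uniformly.

    Discrete parameters are uniform over their levels; continuous ones
    uniform within bounds; the solvent pair is drawn by rejection sampling
    on the unit square so it is exactly uniform on the triangle
    ``et2o + mecn <= 1`` (~50% acceptance).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    out = []
    for _ in range(n):
        vals = {}
        for p in space.parameters:
            if p.name in ("part_et2o", "part_mecn"):
                continue
            if p.is_continuous:
                lo, hi = p.bounds
                vals[p.name] = float(rng.uniform(lo, hi))
            else:
                vals[p.name] = p.levels[rng.integers(len(p.levels))]
        while True:
            a, b = rng.uniform(0.0, 1.0, size=2)
            if a + b <= 1.0:
                break
        vals["part_et2o"], vals["part_mecn"] = float(a), float(b)
        out.append(Conditions(**vals))
    return out


def encode(space: ReactionSpace, c: Conditions) -> np.ndarray:
    """Map conditions to the numeric vector seen by the surrogate.

    Discrete axes carry their registered integer codes (e.g. sieves
    None=0 .. 5A=3, salts by PCA rank); continuous axes are min-max
    scaled to [0, 1].
    """
    violations = validate_conditions(space, c)
    if violations:
        raise ValueError("invalid conditions: " + "; ".join(violations))
    d = c.as_dict()
    v = np.empty(space.dim)
    for i, p in enumerate(space.parameters):
        if p.is_continuous:
            lo, hi = p.bounds
            v[i] = (float(d[p.name]) - lo) / (hi - lo)
        else:
            v[i] = p.code_of(d[p.name])
    return v


def decode(space: ReactionSpace, v: Sequence[float]) -> Conditions:
    """Inverse of :func:`encode`; rejects vectors outside the encoded domain."""
    v = np.asarray(v, dtype=float)
    if v.shape != (space.dim,):
        raise ValueError(f"expected vector of length {space.dim}, got shape {v.shape}")
    vals = {}
    for i, p in enumerate(space.parameters):
        lo, hi = space.axis_range(p)
        if not (lo - 1e-9 <= v[i] <= hi + 1e-9):
            raise ValueError(
                f"axis {p.name}: value {v[i]} outside encoded domain [{lo}, {hi}]"
            )
        if p.is_continuous:
            blo, bhi = p.bounds
            vals[p.name] = float(blo + np.clip(v[i], 0.0, 1.0) * (bhi - blo))
        else:
            code = int(round(v[i]))
            if code not in p.codes:
                raise ValueError(f"axis {p.name}: {v[i]} is not a registered code")
            vals[p.name] = p.label_of(code)
    return Conditions(**vals)


def space_to_config(space: ReactionSpace) -> str:
    """Serialize the space as a plain-text per-parameter block config."""
    lines = []
    for p in space.parameters:
        lines.append(f"[{p.name}]")
        lines.append(f"kind = {p.kind}")
        if p.is_continuous:
            lines.append(f"bounds = {p.bounds[0]}, {p.bounds[1]}")
        else:
            lines.append("levels = " + ", ".join(str(x) for x in p.levels))
            lines.append("codes = " + ", ".join(str(x) for x in p.codes))
        if p.units:
            lines.append(f"units = {p.units}")
        lines.append("")
    lines.append("[constraint]")
    lines.append("rule = part_et2o + part_mecn <= 1")
    return "\n".join(lines) + "\n"
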