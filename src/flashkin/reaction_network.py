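"""Chemical species, reactions and the mass-action rate law.

The chemistry of the water / biological medium is a set of first- and
second-order reactions.  A :class:`ReactionSystem` holds the species
catalogue (with diffusion coefficients, initial concentrations and clamping
flags) and the stoichiometric reaction list, and assembles the right-hand
side of the coupled nonlinear kinetic ODE system

    dc/dt = S @ r(c),      r_j = k_j * c_A [* c_B]

where ``S`` is the net stoichiometry matrix.  An ``A + A`` reaction consumes
two molecules of A per event at rate ``k c_A^2``.  Clamped species (bulk
water, catalyst pools) have their time derivative forced to zero;
boundary-clamped species (dissolved oxygen) are only held fixed at the
lattice borders of the heterogeneous stage.

Reaction and species tables are tab-separated text; the shipped defaults
(``flashkin/data``) cover radiolysis in pure water (reactions 1-39) and in
biological medium (reactions 1-53).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionSystem",
    "SchemaError",
    "ValidationError",
    "load_reaction_system",
    "water_system",
    "biological_system",
    "WATER_MOLARITY",
]

#: Molar concentration of bulk liquid water, M.
WATER_MOLARITY = 55.3

_TRUE = {"1", "true", "yes"}


class SchemaError(ValueError):
    """A table could not be interpreted (missing column, unknown species)."""


class ValidationError(ValueError):
    """A parsed value violates an invariant (e.g. non-positive rate)."""


@dataclass(frozen=True)
class Species:
    """One chemical species.

    Parameters
    ----------
    name:
        Unique identifier (e.g. ``"e_aq"``, ``"ROO"``).
    diffusion_coeff:
        Diffusion coefficient in m^2/s (0 for non-diffusing biomolecules).
    initial_conc:
        Initial molar concentration.
    clamped:
        Concentration held fixed everywhere (bulk water, catalyst pools).
    boundary_clamped:
        Concentration held fixed only in the border cells of the 3-D
        lattice (dissolved oxygen fed from the surroundings).
    """

    name: str
    diffusion_coeff: float = 0.0
    initial_conc: float = 0.0
    clamped: bool = False
    boundary_clamped: bool = False

    def __post_init__(self) -> None:
        if self.diffusion_coeff < 0:
            raise ValidationError(f"{self.name}: diffusion_coeff < 0")
        if self.initial_conc < 0:
            raise ValidationError(f"{self.name}: initial_conc < 0")


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction, first or second order.

    ``reactants`` holds one or two species names (a repeated name encodes an
    A + A reaction); ``products`` may be empty for recombination sinks whose
    products are chemically inert and not tracked.
    """

    id: int
    reactants: tuple[str, ...]
    products: tuple[str, ...] = ()
    rate_constant: float = 0.0
    k_units: str = ""

    def __post_init__(self) -> None:
        if len(self.reactants) not in (1, 2):
            raise ValidationError(f"reaction {self.id}: order must be 1 or 2")
        if not self.rate_constant > 0:
            raise ValidationError(
                f"reaction {self.id}: rate constant must be positive, "
                f"got {self.rate_constant!r}"
            )

    @property
    def order(self) -> int:
        return len(self.reactants)


class ReactionSystem:
    """Species catalogue plus reaction list; the chemical law of motion."""

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        medium: str = "water_only",
    ):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate species name in system")
        if medium not in ("water_only", "biological"):
            raise ValidationError(f"unknown medium {medium!r}")
        self.species: tuple[Species, ...] = tuple(species)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.medium = medium
        self.index: dict[str, int] = {n: i for i, n in enumerate(names)}
        for rx in self.reactions:
            for name in (*rx.reactants, *rx.products):
                if name not in self.index:
                    raise SchemaError(
                        f"reaction {rx.id} references unknown species {name!r}"
                    )
        self._compile()

    # -- compiled arrays -------------------------------------------------
    def _compile(self) -> None:
        ns, nr = len(self.species), len(self.reactions)
        self._i1 = np.zeros(nr, dtype=np.intp)
        self._i2 = np.full(nr, -1, dtype=np.intp)
        self._k = np.array([rx.rate_constant for rx in self.reactions])
        stoich = np.zeros((ns, nr))
        for j, rx in enumerate(self.reactions):
            self._i1[j] = self.index[rx.reactants[0]]
            if rx.order == 2:
                self._i2[j] = self.index[rx.reactants[1]]
            for name in rx.reactants:
                stoich[self.index[name], j] -= 1.0
            for name in rx.products:
                stoich[self.index[name], j] += 1.0
        self._stoich_full = stoich
        self.clamped_mask = np.array([s.clamped for s in self.species])
        self._stoich = stoich.copy()
        self._stoich[self.clamped_mask, :] = 0.0
        self._bimol = self._i2 >= 0

    # -- public surface --------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def initial_concentrations(self) -> np.ndarray:
        return np.array([s.initial_conc for s in self.species])

    def species_index(self, name: str) -> int:
        try:
            return self.index[name]
        except KeyError:
            raise SchemaError(f"species {name!r} not in system") from None

    def reaction_rates(self, conc: np.ndarray) -> np.ndarray:
        """Per-reaction mass-action rates r_j (M/s), no sign checks."""
        conc = np.asarray(conc, dtype=float)
        r = self._k * conc[self._i1]
        r[self._bimol] *= conc[self._i2[self._bimol]]
        return r

    def rate_law(self, conc: np.ndarray) -> np.ndarray:
        """Net d[conc]/dt (M/s) for every species; clamped species get 0.

        Raises
        ------
        ValueError
            If any input concentration is negative.
        """
        conc = np.asarray(conc, dtype=float)
        if conc.shape != (self.n_species,):
            raise ValueError(
                f"conc must have shape ({self.n_species},), got {conc.shape}"
            )
        if np.any(conc < 0):
            raise ValueError("negative input concentration")
        return self._stoich @ self.reaction_rates(conc)

    def rate_law_unchecked(self, conc: np.ndarray) -> np.ndarray:
        """As :meth:`rate_law` but without domain checks (solver internals)."""
        return self._stoich @ self.reaction_rates(conc)

    def jacobian(self, conc: np.ndarray) -> np.ndarray:
        """d(rate_law)/d(conc), dense (n_species, n_species)."""
        conc = np.asarray(conc, dtype=float)
        nr = len(self.reactions)
        dr = np.zeros((nr, self.n_species))
        j = np.arange(nr)
        # d r / d c_i1 = k * (c_i2 | 1);  A+A gives 2 k c via accumulation
        partner = np.ones(nr)
        partner[self._bimol] = conc[self._i2[self._bimol]]
        np.add.at(dr, (j, self._i1), self._k * partner)
        bj = j[self._bimol]
        np.add.at(dr, (bj, self._i2[bj]), self._k[bj] * conc[self._i1[bj]])
        return self._stoich @ dr

    # -- derived systems -------------------------------------------------
    def with_species_conc(self, values: Mapping[str, float]) -> "ReactionSystem":
        """Copy with some initial concentrations replaced (e.g. O2)."""
        sp = [
            replace(s, initial_conc=float(values[s.name]))
            if s.name in values
            else s
            for s in self.species
        ]
        return ReactionSystem(sp, self.reactions, self.medium)

    def with_clamped(self, names: Iterable[str]) -> "ReactionSystem":
        """Copy with additional species concentration-clamped."""
        names = set(names)
        sp = [
            replace(s, clamped=True) if s.name in names else s
            for s in self.species
        ]
        return ReactionSystem(sp, self.reactions, self.medium)

    def subset(self, reaction_ids: Iterable[int]) -> "ReactionSystem":
        """Copy keeping only the listed reaction ids (species unchanged)."""
        keep = set(reaction_ids)
        rxns = [rx for rx in self.reactions if rx.id in keep]
        return ReactionSystem(self.species, rxns, self.medium)

    def perturbed(
        self,
        rate_factors: Mapping[int, float] | None = None,
        conc_factors: Mapping[str, float] | None = None,
    ) -> "ReactionSystem":
        """Copy with rate constants / initial concentrations multiplied.

        Used by the sensitivity harness: ``rate_factors`` maps reaction id to
        a multiplier, ``conc_factors`` maps species name to a multiplier.
        """
        rate_factors = rate_factors or {}
        conc_factors = conc_factors or {}
        rxns = [
            replace(rx, rate_constant=rx.rate_constant * rate_factors.get(rx.id, 1.0))
            for rx in self.reactions
        ]
        sp = [
            replace(s, initial_conc=s.initial_conc * conc_factors.get(s.name, 1.0))
            for s in self.species
        ]
        return ReactionSystem(sp, rxns, self.medium)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def _read_rows(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty table")
        return [row for row in reader if any((v or "").strip() for v in row.values())]


def _parse_species_table(path: str | Path) -> list[Species]:
    required = {"name", "diffusion_1e-9_m2_s", "initial_conc_M", "clamped",
                "boundary_clamped"}
    rows = _read_rows(path)
    if rows and not required.issubset(rows[0]):
        missing = required - set(rows[0])
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in rows:
        try:
            out.append(
                Species(
                    name=row["name"].strip(),
                    diffusion_coeff=float(row["diffusion_1e-9_m2_s"]) * 1e-9,
                    initial_conc=float(row["initial_conc_M"]),
                    clamped=row["clamped"].strip().lower() in _TRUE,
                    boundary_clamped=row["boundary_clamped"].strip().lower() in _TRUE,
                )
            )
        except (KeyError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise SchemaError(f"{path}: bad species row {row!r}: {exc}") from exc
    return out


def _parse_reaction_table(path: str | Path) -> list[Reaction]:
    required = {"id", "reactant1", "reactant2", "products", "k", "k_units"}
    rows = _read_rows(path)
    if rows and not required.issubset(rows[0]):
        missing = required - set(rows[0])
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in rows:
        try:
            reactants = [row["reactant1"].strip()]
            r2 = (row["reactant2"] or "").strip()
            if r2:
                reactants.append(r2)
            prod = (row["products"] or "").strip()
            products = tuple(p.strip() for p in prod.split(";") if p.strip())
            out.append(
                Reaction(
                    id=int(row["id"]),
                    reactants=tuple(reactants),
                    products=products,
                    rate_constant=float(row["k"]),
                    k_units=(row["k_units"] or "").strip(),
                )
            )
        except (KeyError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise SchemaError(f"{path}: bad reaction row {row!r}: {exc}") from exc
    return out


def load_reaction_system(
    species_table: str | Path,
    reaction_table: str | Path,
    medium: str | None = None,
) -> ReactionSystem:
    """Load and validate a :class:`ReactionSystem` from two TSV tables.

    ``medium`` is inferred from the reaction ids when not given: a table
    containing any reaction with id >= 40 is ``"biological"``.
    """
    species = _parse_species_table(species_table)
    reactions = _parse_reaction_table(reaction_table)
    if medium is None:
        medium = (
            "biological"
            if any(rx.id >= 40 for rx in reactions)
            else "water_only"
        )
    return ReactionSystem(species, reactions, medium)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("flashkin").joinpath("data", name)))


def water_system() -> ReactionSystem:
    """The shipped pure-water radiolysis system (reactions 1-39)."""
    return load_reaction_system(
        _data_path("species_water.tsv"), _data_path("reactions_water.tsv")
    )


def biological_system() -> ReactionSystem:
    """The shipped biological-medium system (reactions 1-53)."""
    return load_reaction_system(
        _data_path("species_biological.tsv"),
        _data_path("reactions_biological.tsv"),
    )
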