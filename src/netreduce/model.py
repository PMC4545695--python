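"""Core data model: stoichiometric networks, scenarios, protection specs.

A :class:`MetabolicModel` is the shared in-memory container for every other
module.  Its stoichiometric matrix ``S`` covers *internal* (balanced)
metabolites only; boundary/external species are kept in a separate matrix
``S_ext`` purely for bookkeeping (they impose no steady-state constraint but
must survive compression so that, e.g., a trace element absorbed into a
condensed biomass reaction remains visible).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np


class ModelError(ValueError):
    """Raised for malformed models, specs, or files."""


@dataclass
class MetabolicModel:
    """Stoichiometric network with flux bounds and a linear objective.

    Parameters
    ----------
    metabolite_ids
        Ordered internal metabolite identifiers (rows of ``S``).
    reaction_ids
        Ordered reaction identifiers (columns of ``S``).
    S
        Dense ``m x n`` stoichiometric matrix over internal metabolites.
    lower_bounds, upper_bounds
        Per-reaction flux bounds; ``-inf``/``+inf`` allowed.
    objective
        Per-reaction linear objective coefficients (FBA maximises ``c @ r``).
    external_species
        Boundary species identifiers (rows of ``S_ext``, not balanced).
    S_ext
        ``len(external_species) x n`` matrix of boundary stoichiometry.
    compartments
        Optional per-internal-metabolite compartment tags.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    objective: np.ndarray
    external_species: list[str] = field(default_factory=list)
    S_ext: np.ndarray | None = None
    compartments: dict[str, str] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self) -> None:
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        if self.S.size == 0:
            self.S = self.S.reshape(len(self.metabolite_ids), len(self.reaction_ids))
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        if self.S_ext is None:
            self.S_ext = np.zeros((len(self.external_species), self.n_reactions))
        else:
            self.S_ext = np.atleast_2d(np.asarray(self.S_ext, dtype=float))
            if self.S_ext.size == 0:
                self.S_ext = self.S_ext.reshape(
                    len(self.external_species), self.n_reactions
                )
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def reaction_index(self, rid: str) -> int:
        try:
            return self._rxn_index[rid]
        except AttributeError:
            self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
            return self._rxn_index[rid]
        except KeyError:
            raise ModelError(f"unknown reaction {rid!r}") from None

    def metabolite_index(self, mid: str) -> int:
        try:
            return self.metabolite_ids.index(mid)
        except ValueError:
            raise ModelError(f"unknown metabolite {mid!r}") from None

    def validate(self) -> None:
        m, n = self.S.shape
        if m != len(self.metabolite_ids):
            raise ModelError(
                f"S has {m} rows but {len(self.metabolite_ids)} metabolite ids"
            )
        if n != len(self.reaction_ids):
            raise ModelError(
                f"S has {n} columns but {len(self.reaction_ids)} reaction ids"
            )
        for arr, label in (
            (self.lower_bounds, "lower_bounds"),
            (self.upper_bounds, "upper_bounds"),
            (self.objective, "objective"),
        ):
            if arr.shape != (n,):
                raise ModelError(f"{label} must have length {n}, got {arr.shape}")
        if len(set(self.metabolite_ids)) != m:
            raise ModelError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != n:
            raise ModelError("duplicate reaction ids")
        dup = set(self.metabolite_ids) & set(self.external_species)
        if dup:
            raise ModelError(f"ids both internal and external: {sorted(dup)}")
        bad = np.nonzero(self.lower_bounds > self.upper_bounds)[0]
        if bad.size:
            rid = self.reaction_ids[int(bad[0])]
            raise ModelError(f"lower bound exceeds upper bound for reaction {rid!r}")
        # every reaction must touch something: internal or explicit boundary
        touch = (np.abs(self.S) > 0).any(axis=0)
        if self.S_ext is not None and self.S_ext.shape[0]:
            touch |= (np.abs(self.S_ext) > 0).any(axis=0)
        empty = np.nonzero(~touch)[0]
        if empty.size:
            rid = self.reaction_ids[int(empty[0])]
            raise ModelError(f"reaction {rid!r} has all-zero stoichiometry")
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}

    # -- derived views ---------------------------------------------------
    def reversibilities(self) -> np.ndarray:
        """A reaction is reversible iff its lower bound is negative."""
        return self.lower_bounds < 0

    def reaction_stoichiometry(self, rid: str) -> dict[str, float]:
        """Signed coefficients of one reaction over internal + external species."""
        j = self.reaction_index(rid)
        out: dict[str, float] = {}
        for i, mid in enumerate(self.metabolite_ids):
            if self.S[i, j] != 0:
                out[mid] = float(self.S[i, j])
        for i, mid in enumerate(self.external_species):
            if self.S_ext[i, j] != 0:
                out[mid] = float(self.S_ext[i, j])
        return out

    # -- editing (copy-on-write style) ----------------------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            objective=self.objective.copy(),
            external_species=list(self.external_species),
            S_ext=self.S_ext.copy(),
            compartments=dict(self.compartments),
            name=self.name,
        )

    def drop_reactions(self, rids: Iterable[str]) -> "MetabolicModel":
        """Return a copy with the given reaction columns removed."""
        drop = set(rids)
        keep = [j for j, r in enumerate(self.reaction_ids) if r not in drop]
        missing = drop - set(self.reaction_ids)
        if missing:
            raise ModelError(f"cannot drop unknown reactions {sorted(missing)}")
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=[self.reaction_ids[j] for j in keep],
            S=self.S[:, keep],
            lower_bounds=self.lower_bounds[keep],
            upper_bounds=self.upper_bounds[keep],
            objective=self.objective[keep],
            external_species=list(self.external_species),
            S_ext=self.S_ext[:, keep],
            compartments=dict(self.compartments),
            name=self.name,
        )

    def drop_unconnected_metabolites(
        self, keep: Iterable[str] = ()
    ) -> tuple["MetabolicModel", list[str]]:
        """Remove internal metabolites participating in no reaction.

        Metabolites named in *keep* (e.g. protected ones) are always retained.
        Returns the new model and the list of removed metabolite ids.
        """
        keep = set(keep)
        connected = (np.abs(self.S) > 0).any(axis=1)
        rows = [
            i
            for i, mid in enumerate(self.metabolite_ids)
            if connected[i] or mid in keep
        ]
        removed = [
            mid for i, mid in enumerate(self.metabolite_ids) if i not in set(rows)
        ]
        if not removed:
            return self, []
        model = MetabolicModel(
            metabolite_ids=[self.metabolite_ids[i] for i in rows],
            reaction_ids=list(self.reaction_ids),
            S=self.S[rows, :],
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            objective=self.objective.copy(),
            external_species=list(self.external_species),
            S_ext=self.S_ext.copy(),
            compartments={
                k: v for k, v in self.compartments.items() if k not in set(removed)
            },
            name=self.name,
        )
        return model, removed


@dataclass(frozen=True)
class LinearConstraint:
    """One normalised inequality ``sum(coefs[r] * flux[r]) <= rhs``."""

    coefs: tuple[tuple[str, float], ...]
    rhs: float

    @staticmethod
    def make(coefs: Mapping[str, float], rhs: float) -> "LinearConstraint":
        items = tuple(sorted((r, float(c)) for r, c in coefs.items() if c != 0))
        return LinearConstraint(items, float(rhs))

    def as_dict(self) -> dict[str, float]:
        return dict(self.coefs)


@dataclass
class Scenario:
    """A protected function/phenotype: linear inequalities over named fluxes.

    All relations are normalised to ``<=``: a ``>=`` is stored negated and an
    ``==`` as a pair of opposite inequalities, so applying the constraints is
    order-independent and idempotent.  Optional per-reaction
    ``bound_overrides`` replace the model bounds within this scenario only.
    """

    name: str
    constraints: list[LinearConstraint] = field(default_factory=list)
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def add(self, coefs: Mapping[str, float], relation: str, rhs: float) -> None:
        if relation in ("<=", "<"):
            self.constraints.append(LinearConstraint.make(coefs, rhs))
        elif relation in (">=", ">"):
            self.constraints.append(
                LinearConstraint.make({r: -c for r, c in coefs.items()}, -rhs)
            )
        elif relation in ("==", "="):
            self.add(coefs, "<=", rhs)
            self.add(coefs, ">=", rhs)
        else:
            raise ModelError(f"unsupported relation {relation!r}")

    def referenced_reactions(self) -> set[str]:
        refs = {r for c in self.constraints for r, _ in c.coefs}
        refs.update(self.bound_overrides)
        return refs

    def validate_against(self, model: MetabolicModel) -> None:
        unknown = self.referenced_reactions() - set(model.reaction_ids)
        if unknown:
            raise ModelError(
                f"scenario {self.name!r} references unknown reactions "
                f"{sorted(unknown)}"
            )


@dataclass
class ProtectionSpec:
    """What the reduction must preserve.

    Attributes
    ----------
    protected_metabolites
        Metabolites that must stay in the network, each touched by at least
        one feasible (non-blocked) reaction.
    protected_reactions
        Reactions that are never deleted (and never lumped away).
    enforce_protected_feasibility
        If true, every protected reaction must be able to carry nonzero flux
        in at least one protected scenario.
    scenarios
        Protected phenotypes; each must stay feasible throughout pruning.
    dof_min
        Floor on the degrees of freedom (``n - rank(S)``) of the reduced net.
    n_min
        Floor on the number of remaining reactions.
    """

    protected_metabolites: set[str] = field(default_factory=set)
    protected_reactions: set[str] = field(default_factory=set)
    enforce_protected_feasibility: bool = False
    scenarios: list[Scenario] = field(default_factory=list)
    dof_min: int = 1
    n_min: int = 1

    def __post_init__(self) -> None:
        self.protected_metabolites = set(self.protected_metabolites)
        self.protected_reactions = set(self.protected_reactions)
        if self.dof_min < 0:
            raise ModelError("dof_min must be >= 0")
        if self.n_min < 1:
            raise ModelError("n_min must be >= 1")

    def validate_against(self, model: MetabolicModel) -> None:
        bad_m = self.protected_metabolites - set(model.metabolite_ids)
        if bad_m:
            raise ModelError(f"protected metabolites not in model: {sorted(bad_m)}")
        bad_r = self.protected_reactions - set(model.reaction_ids)
        if bad_r:
            raise ModelError(f"protected reactions not in model: {sorted(bad_r)}")
        for sc in self.scenarios:
            sc.validate_against(model)
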