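"""Bead roles, interaction tables, engine parameters and the unit system.

Internal unit system (shared by every module):

* length   — Å
* time     — fs
* energy   — kcal/mol
* mass     — Da (g/mol)
* velocity — Å/fs

Pairwise attraction strengths are quoted in units of ``k_B T`` at a
reference temperature and converted to kcal/mol exactly once, when a force
field is assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "K_B_KCAL",
    "N_AVOGADRO",
    "KCAL_MOL_TO_DA_A2_FS2",
    "BeadRole",
    "InteractionTable",
    "EngineParams",
    "ChainSpec",
    "SystemSpec",
    "kBT_to_kcal",
    "kcal_to_kBT",
    "build_interaction_table",
]

#: Boltzmann constant, kcal/mol/K (fixed constant, not library-dependent).
K_B_KCAL = 0.0019872041

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: 1 kcal/mol expressed in Da Å²/fs² (4184 J/mol ÷ 1e7 (g/mol)(Å/fs)²).
KCAL_MOL_TO_DA_A2_FS2 = 4.184e-4


class BeadRole(IntEnum):
    """The four bead roles of the coarse-grained model.

    ``SPECIFIC`` beads form the strong, exclusive interaction patch;
    ``NONSPECIFIC`` beads interact weakly and promiscuously; ``INERT``
    beads are purely repulsive volume; ``ALT_NONSPECIFIC`` beads behave
    like nonspecific beads among themselves and toward the patch but are
    repulsive toward plain nonspecific beads (two-cluster mixtures).
    """

    SPECIFIC = 0
    NONSPECIFIC = 1
    INERT = 2
    ALT_NONSPECIFIC = 3

    @property
    def label(self) -> str:
        return _ROLE_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "BeadRole":
        try:
            return _LABEL_ROLES[label]
        except KeyError:
            raise ValueError(f"unknown bead role label: {label!r}") from None


_ROLE_LABELS = {
    BeadRole.SPECIFIC: "specific",
    BeadRole.NONSPECIFIC: "nonspecific",
    BeadRole.INERT: "inert",
    BeadRole.ALT_NONSPECIFIC: "alt_nonspecific",
}
_LABEL_ROLES = {v: k for k, v in _ROLE_LABELS.items()}

N_ROLES = len(BeadRole)


def kBT_to_kcal(eps: float, T_ref: float) -> float:
    """Convert an energy from k_B T units at ``T_ref`` (K) to kcal/mol.

    Raises
    ------
    ValueError
        If ``eps`` is negative or ``T_ref`` is not positive.
    """
    if eps < 0:
        raise ValueError(f"energy in k_B T units must be non-negative, got {eps}")
    if T_ref <= 0:
        raise ValueError(f"reference temperature must be positive, got {T_ref}")
    return eps * K_B_KCAL * T_ref


def kcal_to_kBT(e_kcal: float, T_ref: float) -> float:
    """Convert an energy from kcal/mol to k_B T units at ``T_ref`` (K)."""
    if T_ref <= 0:
        raise ValueError(f"reference temperature must be positive, got {T_ref}")
    return e_kcal / (K_B_KCAL * T_ref)


@dataclass(frozen=True)
class InteractionTable:
    """Symmetric pairwise interaction strengths per unordered role pair.

    ``eps`` holds attraction depths in k_B T units at ``T_ref``;
    ``attractive`` marks which pairs use the full attractive potential
    (cut at 2.5 σ) versus the purely repulsive branch (cut at 2^(1/6) σ
    with a fixed depth of 1 k_B T at ``T_ref``).
    """

    eps_sp: float
    eps_ns: float
    T_ref: float
    eps: np.ndarray  # (4, 4) float, k_B T units
    attractive: np.ndarray  # (4, 4) bool

    def __post_init__(self) -> None:
        if self.eps.shape != (N_ROLES, N_ROLES):
            raise ValueError("eps must be a 4x4 matrix")
        if not np.allclose(self.eps, self.eps.T):
            raise ValueError("interaction table must be symmetric in role order")
        if not np.array_equal(self.attractive, self.attractive.T):
            raise ValueError("interaction modes must be symmetric in role order")
        if not self.eps_sp > self.eps_ns:
            raise ValueError(
                "the model requires the specific attraction to exceed the "
                f"non-specific one (eps_sp > eps_ns); got eps_sp={self.eps_sp}, "
                f"eps_ns={self.eps_ns}"
            )

    def lookup(self, a: BeadRole, b: BeadRole) -> tuple[float, str]:
        """Return ``(depth in k_B T, mode)`` for a role pair.

        ``mode`` is ``"attractive"`` or ``"repulsive_only"``.
        """
        mode = "attractive" if self.attractive[a, b] else "repulsive_only"
        return float(self.eps[a, b]), mode

    def eps_kcal(self) -> np.ndarray:
        """Pair depths converted to kcal/mol.

        Repulsive-only pairs get a depth of 1 k_B T at ``T_ref`` (the depth
        only sets the steepness of the repulsive wall).
        """
        depth = np.where(self.attractive, self.eps, 1.0)
        return np.vectorize(lambda e: kBT_to_kcal(float(e), self.T_ref))(depth)


def build_interaction_table(
    eps_sp: float,
    eps_ns: float,
    system_kind: str = "default",
    T_ref: float = 310.0,
) -> InteractionTable:
    """Build the role-pair interaction table.

    The mapping is identical for all three system kinds (the kinds differ
    only in chain composition): specific–specific attracts with ``eps_sp``;
    nonspecific–nonspecific and nonspecific–specific attract with
    ``eps_ns``; inert pairs are repulsive-only toward everything;
    alt_nonspecific attracts itself and the specific patch with ``eps_ns``
    but is repulsive-only toward plain nonspecific beads.
    """
    if system_kind not in ("default", "system1", "system2"):
        raise ValueError(f"unknown system kind: {system_kind!r}")
    if eps_ns < 0:
        raise ValueError(f"eps_ns must be non-negative, got {eps_ns}")
    if not eps_sp > eps_ns:
        raise ValueError(
            "the model requires eps_sp > eps_ns (specific attraction stronger "
            f"than non-specific); got eps_sp={eps_sp}, eps_ns={eps_ns}"
        )

    S, B, K, G = (
        BeadRole.SPECIFIC,
        BeadRole.NONSPECIFIC,
        BeadRole.INERT,
        BeadRole.ALT_NONSPECIFIC,
    )
    eps = np.zeros((N_ROLES, N_ROLES))
    attr = np.zeros((N_ROLES, N_ROLES), dtype=bool)

    def set_pair(a: BeadRole, b: BeadRole, depth: float, attractive: bool) -> None:
        eps[a, b] = eps[b, a] = depth
        attr[a, b] = attr[b, a] = attractive

    set_pair(S, S, eps_sp, True)
    set_pair(B, B, eps_ns, True)
    set_pair(B, S, eps_ns, True)
    set_pair(G, G, eps_ns, True)
    set_pair(G, S, eps_ns, True)
    set_pair(G, B, 0.0, False)
    for other in (S, B, K, G):
        set_pair(K, other, 0.0, False)

    return InteractionTable(
        eps_sp=eps_sp, eps_ns=eps_ns, T_ref=T_ref, eps=eps, attractive=attr
    )


@dataclass(frozen=True)
class EngineParams:
    """Langevin engine parameters (defaults are the stock parameter set)."""

    k_s: float = 10.0  # kcal/mol/Å² (note: no 1/2 prefactor in the bond term)
    r0: float = 4.5  # Å
    kappa: float = 2.0  # kcal/mol
    sigma: float = 4.5  # Å
    dt: float = 30.0  # fs
    T: float = 310.0  # K
    damping_time: float = 1.2e3  # fs (1.2 ps)
    bead_mass: float = 110.0  # Da

    def __post_init__(self) -> None:
        for name in (
            "k_s",
            "r0",
            "kappa",
            "sigma",
            "dt",
            "T",
            "damping_time",
            "bead_mass",
        ):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"EngineParams.{name} must be strictly positive, got {value}")

    @property
    def r_cut_attr(self) -> float:
        """Attractive pair cutoff, 2.5 σ (Å)."""
        return 2.5 * self.sigma

    @property
    def r_cut_rep(self) -> float:
        """Repulsive-only pair cutoff, 2^(1/6) σ (Å)."""
        return 2.0 ** (1.0 / 6.0) * self.sigma

    @property
    def kT(self) -> float:
        """Thermal energy at the set temperature, kcal/mol."""
        return K_B_KCAL * self.T


@dataclass(frozen=True)
class ChainSpec:
    """A single chain's bead-role layout."""

    roles: tuple[BeadRole, ...]
    n_frac: float | None = None  # percent of non-core beads that attract

    def __post_init__(self) -> None:
        if len(self.roles) < 1:
            raise ValueError("a chain needs at least one bead")
        if self.n_frac is not None and not (0.0 <= self.n_frac <= 100.0):
            raise ValueError(f"n_frac must lie in [0, 100], got {self.n_frac}")

    @property
    def length(self) -> int:
        return len(self.roles)

    @classmethod
    def from_role_string(cls, text: str, n_frac: float | None = None) -> "ChainSpec":
        """Parse a run-length role string such as ``"36B-7R-37B"``.

        Letters: R = specific, B = nonspecific, K = inert,
        G = alt_nonspecific.
        """
        letters = {
            "R": BeadRole.SPECIFIC,
            "B": BeadRole.NONSPECIFIC,
            "K": BeadRole.INERT,
            "G": BeadRole.ALT_NONSPECIFIC,
        }
        roles: list[BeadRole] = []
        for part in text.split("-"):
            part = part.strip()
            if not part or part[-1].upper() not in letters or not part[:-1].isdigit():
                raise ValueError(f"bad role run {part!r} in role string {text!r}")
            roles.extend([letters[part[-1].upper()]] * int(part[:-1]))
        return cls(roles=tuple(roles), n_frac=n_frac)

    def role_string(self) -> str:
        """Run-length encoding such as ``"36B-7R-37B"``."""
        letters = {
            BeadRole.SPECIFIC: "R",
            BeadRole.NONSPECIFIC: "B",
            BeadRole.INERT: "K",
            BeadRole.ALT_NONSPECIFIC: "G",
        }
        parts: list[str] = []
        run_role, run_len = self.roles[0], 0
        for role in self.roles:
            if role == run_role:
                run_len += 1
            else:
                parts.append(f"{run_len}{letters[run_role]}")
                run_role, run_len = role, 1
        parts.append(f"{run_len}{letters[run_role]}")
        return "-".join(parts)


@dataclass(frozen=True)
class SystemSpec:
    """Chain composition plus box geometry and the build seed.

    Exactly one of ``box_edge`` (Å) or ``concentration`` (mol/L, box edge
    derived from the total chain count) must be given.
    """

    chains: tuple[tuple[ChainSpec, int], ...]
    seed: int
    box_edge: float | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        if (self.box_edge is None) == (self.concentration is None):
            raise ValueError("give exactly one of box_edge or concentration")
        if self.box_edge is not None and self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        if self.concentration is not None and self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not self.chains:
            raise ValueError("a system needs at least one chain")
        for _, count in self.chains:
            if count < 1:
                raise ValueError("chain counts must be >= 1")

    @property
    def n_chains(self) -> int:
        return sum(count for _, count in self.chains)

    @property
    def n_beads(self) -> int:
        return sum(spec.length * count for spec, count in self.chains)

    def resolve_box_edge(self) -> float:
        """Box edge in Å, deriving it from the concentration if needed."""
        if self.box_edge is not None:
            return self.box_edge
        from .builder import box_from_concentration

        return box_from_concentration(self.n_chains, self.concentration)
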