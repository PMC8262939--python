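"""Host-phage resource-competition models of restriction-modification defense.

Three deterministic ODE models describe competition of bacterial populations
for a single nutrient in the presence of lytic phage.  Populations differ only
in the set of restriction-modification (RM) systems they carry: each RM
multiplies phage susceptibility by ``1/r_e`` but costs a fixed fraction of
nutrient-utilization ability.

* **general** -- one generalist phage infects every host.
* **parallel** -- one phage per host; no cross-infection.
* **memory** -- one phage per host; every phage can infect every host, but
  progeny inherit the methylation pattern of the host they burst from, so a
  phage partially or fully evades RM systems shared with its previous host.

RM identities are opaque labels held in frozensets; protection depends only on
set cardinalities (difference and intersection with the phage methylome).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RMSet",
    "rm_set",
    "ModelKind",
    "HostSpec",
    "PhageSpec",
    "ModelParams",
    "CommunityState",
    "total_cost",
    "gamma_coefficient",
    "gamma_matrix",
    "derivatives",
    "analytic_equilibria",
    "viral_persistence_threshold",
]

#: An RM complement (of a host) or methylation pattern (of a virion):
#: a frozenset of opaque RM-system labels.
RMSet = frozenset


def rm_set(*members: str) -> RMSet:
    """Build an :data:`RMSet` from labels, e.g. ``rm_set("r1", "r2")``."""
    return frozenset(members)


class ModelKind(str, enum.Enum):
    """Which virus-host interaction structure is simulated."""

    GENERAL = "general"
    PARALLEL = "parallel"
    MEMORY = "memory"


@dataclass(frozen=True)
class HostSpec:
    """A bacterial population defined by its RM complement.

    Parameters
    ----------
    id : str
        Population label.
    rm_set : RMSet
        The RM systems carried (``b_i``).
    alpha : float, optional
        Per-population nutrient utilization rate (ml cell^-1 day^-1).
        ``None`` means use the shared value from :class:`ModelParams`.
    per_rm_cost : float
        Fractional loss of nutrient utilization per RM system; the total
        cost is linear in the number of RMs and must stay below 1.
    """

    id: str
    rm_set: RMSet = field(default_factory=frozenset)
    alpha: float | None = None
    per_rm_cost: float = 0.05

    def __post_init__(self) -> None:
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError(f"host {self.id}: alpha must be > 0")
        total_cost(self.rm_set, self.per_rm_cost)  # validates cost < 1

    def cost(self) -> float:
        return total_cost(self.rm_set, self.per_rm_cost)


@dataclass(frozen=True)
class PhageSpec:
    """A phage population and, in the memory model, its methylation pattern.

    ``host_index`` names the single host population whose bursts produce this
    phage; in the memory model the phage's methylation equals that host's RM
    set (progeny adopt the methylome of the cell they lysed).
    """

    id: str
    methylation: RMSet = field(default_factory=frozenset)
    host_index: int = 0


@dataclass(frozen=True)
class ModelParams:
    """Rate constants shared by all three models.

    Attributes
    ----------
    S : float
        Nutrient supply rate (cellular equivalents ml^-1 day^-1).
    alpha : float
        Nutrient utilization rate (ml cell^-1 day^-1).
    phi : float
        Baseline infection-rate constant (ml virus^-1 day^-1).
    r_e : float
        Resistance gained per RM endonuclease (fold, >= 1).
    m_v : float
        Virion methylation: fraction of restriction sites in progeny
        genomes carrying the host's methylation pattern, in [0, 1].
    beta : float
        Burst size (virus cell^-1).
    delta_b, delta_p : float
        Host and phage loss rates (day^-1).
    """

    S: float = 1e6
    alpha: float = 1e-7
    phi: float = 1e-6
    r_e: float = 100.0
    m_v: float = 0.99
    beta: float = 50.0
    delta_b: float = 0.1
    delta_p: float = 0.5

    def __post_init__(self) -> None:
        for name in ("S", "alpha", "phi", "beta", "delta_b", "delta_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.r_e < 1:
            raise ValueError("r_e must be >= 1 (an RM cannot aid infection)")
        if not 0.0 <= self.m_v <= 1.0:
            raise ValueError("m_v must lie in [0, 1]")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")

    def with_(self, **kw) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


@dataclass
class CommunityState:
    """Nutrient concentration plus host and phage abundance vectors."""

    N: float
    B: np.ndarray
    P: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.P = np.asarray(self.P, dtype=float)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([[self.N], self.B, self.P])

    @classmethod
    def from_vector(cls, y: np.ndarray, n_hosts: int, t: float = 0.0) -> "CommunityState":
        y = np.asarray(y, dtype=float)
        return cls(N=y[0], B=y[1 : 1 + n_hosts], P=y[1 + n_hosts :], t=t)

    def validate(self, n_hosts: int, n_phages: int) -> None:
        if self.B.shape != (n_hosts,) or self.P.shape != (n_phages,):
            raise ValueError(
                f"state dimensions ({self.B.size} hosts, {self.P.size} phages) "
                f"do not match community ({n_hosts} hosts, {n_phages} phages)"
            )
        if self.N < 0 or (self.B < 0).any() or (self.P < 0).any():
            raise ValueError("negative abundances are not a valid state")


def total_cost(rm_set: RMSet, per_rm_cost: float) -> float:
    """Total defense cost ``c``: the fraction of nutrient utilization lost.

    Cost is strictly linear in the number of RM systems (one RM at cost 0.05
    gives c = 0.05, two give c = 0.10) and scales utilization as
    ``alpha * (1 - c)``.  A total cost reaching 1 would abolish growth
    entirely and is rejected as a configuration error rather than clamped.
    """
    if per_rm_cost < 0:
        raise ValueError("per_rm_cost must be >= 0")
    c = per_rm_cost * len(rm_set)
    if c >= 1.0:
        raise ValueError(
            f"total RM cost {c:.3g} (= {per_rm_cost} x {len(rm_set)} RMs) must be < 1"
        )
    return c


def gamma_coefficient(b: RMSet, r_e: float) -> float:
    """Susceptibility of a host carrying RM set ``b`` to unmethylated phage.

    Protection is multiplicative across RM systems: gamma = r_e ** -|b|,
    which multiplies the baseline infection rate phi.  gamma = 1 for an
    undefended host; |b| = 2 with r_e = 100 gives 1e-4 (a 10,000-fold
    infection reduction).
    """
    if r_e < 1:
        raise ValueError("r_e must be >= 1")
    return float(r_e) ** -len(b)


def gamma_matrix(
    host_sets: list[RMSet],
    phage_sets: list[RMSet],
    r_e: float,
    m_v: float,
) -> np.ndarray:
    """Pairwise susceptibility matrix Gamma for the memory model.

    ``Gamma[i, j] = r_e ** -( |b_i - p_j| + (1 - m_v) * |b_i & p_j| )``:
    RMs the phage is not methylated against act at full strength; RMs shared
    with the phage methylome are discounted by the virion methylation m_v.
    With m_v = 0 every column reduces to :func:`gamma_coefficient` (no
    memory); with m_v = 1 shared RMs are fully evaded.
    """
    if r_e < 1:
        raise ValueError("r_e must be >= 1")
    if not 0.0 <= m_v <= 1.0:
        raise ValueError("m_v must lie in [0, 1]")
    G = np.empty((len(host_sets), len(phage_sets)))
    for i, b in enumerate(host_sets):
        for j, p in enumerate(phage_sets):
            exponent = len(b - p) + (1.0 - m_v) * len(b & p)
            G[i, j] = float(r_e) ** -exponent
    return G


def _effective_rates(hosts: list[HostSpec], params: ModelParams) -> np.ndarray:
    """alpha_i * (1 - c_i) for each host."""
    return np.array(
        [(h.alpha if h.alpha is not None else params.alpha) * (1.0 - h.cost()) for h in hosts]
    )


def _check_structure(
    kind: ModelKind, hosts: list[HostSpec], phages: list[PhageSpec]
) -> None:
    kind = ModelKind(kind)
    if not hosts:
        raise ValueError("at least one host population is required")
    if kind is ModelKind.GENERAL:
        if len(phages) != 1:
            raise ValueError("general model has exactly one phage population")
    else:
        if len(phages) != len(hosts):
            raise ValueError(f"{kind.value} model needs one phage per host")
        idx = [p.host_index for p in phages]
        if idx != list(range(len(hosts))):
            raise ValueError(
                "phage j must be the phage produced by host j (host_index == position)"
            )


class CompiledModel:
    """Precomputed right-hand side for one (kind, hosts, phages, params).

    Builds the effective utilization rates and susceptibility structure once
    so that the RHS evaluated inside the ODE solver is pure numpy.
    """

    def __init__(
        self,
        kind: ModelKind,
        hosts: list[HostSpec],
        phages: list[PhageSpec],
        params: ModelParams,
    ):
        kind = ModelKind(kind)
        _check_structure(kind, hosts, phages)
        self.kind = kind
        self.hosts = hosts
        self.phages = phages
        self.params = params
        self.n_hosts = len(hosts)
        self.n_phages = len(phages)
        self.au = _effective_rates(hosts, params)  # alpha_i (1 - c_i)
        host_sets = [h.rm_set for h in hosts]
        if kind is ModelKind.MEMORY:
            self.G = gamma_matrix(
                host_sets, [p.methylation for p in phages], params.r_e, params.m_v
            )
        else:
            self.gamma = np.array(
                [gamma_coefficient(b, params.r_e) for b in host_sets]
            )

    #: Log-space floor for population abundances during integration.  A
    #: population pinned here (~1e-30 cells/ml) is dynamically extinct but can
    #: still re-invade if its per-capita growth rate turns positive, mirroring
    #: the fact that a deterministic ODE never reaches exactly zero.
    LOG_FLOOR = float(np.log(1e-30))

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        # Small negative solver excursions are treated as zero: the growth
        # terms are linear in each population, so a negative value on a
        # growing population would otherwise run away along the unphysical
        # negative branch.
        y = np.maximum(y, 0.0)
        p = self.params
        n = self.n_hosts
        N, B, P = y[0], y[1 : 1 + n], y[1 + n :]
        uptake = self.au * B * N
        dN = p.S - uptake.sum()
        if self.kind is ModelKind.GENERAL:
            infections = p.phi * self.gamma * B * P[0]  # per-host infection losses
            dB = uptake - infections - p.delta_b * B
            dP = np.array([p.beta * infections.sum() - p.delta_p * P[0]])
        elif self.kind is ModelKind.PARALLEL:
            infections = p.phi * self.gamma * B * P
            dB = uptake - infections - p.delta_b * B
            dP = p.beta * infections - p.delta_p * P
        else:  # memory
            # infection of host i by phage j at rate phi * Gamma_ij * B_i * P_j;
            # every burst from host i releases phage of type i
            inf_matrix = p.phi * self.G * B[:, None] * P[None, :]
            dB = uptake - inf_matrix.sum(axis=1) - p.delta_b * B
            dP = p.beta * inf_matrix.sum(axis=1) - p.delta_p * P
        return np.concatenate([[dN], dB, dP])

    def to_log_state(self, y: np.ndarray) -> np.ndarray:
        """Linear state -> mixed state [N, log B, log P], flooring zeros."""
        z = np.array(y, dtype=float)
        z[1:] = np.log(np.maximum(z[1:], np.exp(self.LOG_FLOOR)))
        return z

    def from_log_state(self, z: np.ndarray) -> np.ndarray:
        y = np.array(z, dtype=float)
        y[0] = max(y[0], 0.0)
        y[1:] = np.exp(np.minimum(y[1:], 700.0))
        return y

    def rhs_log(self, t: float, z: np.ndarray) -> np.ndarray:
        """RHS in mixed coordinates: nutrient linear, populations in log.

        Log coordinates keep deep transient population crashes (which can
        pass far below any absolute solver tolerance) representable, so a
        population that would rebound is not spuriously zeroed.  At the log
        floor a declining population is held in place (reflecting floor).
        """
        y = self.from_log_state(z)
        dy = self.rhs(t, y)
        du = dy.copy()
        du[1:] = dy[1:] / y[1:]
        # continuous floor: decay rates ramp to zero over the last nat above
        # the floor, so the solver sees no derivative discontinuity
        ramp = np.clip(z[1:] - self.LOG_FLOOR, 0.0, 1.0)
        du[1:] = np.where(du[1:] < 0, du[1:] * ramp, du[1:])
        return du


def derivatives(
    kind: ModelKind,
    state: CommunityState,
    hosts: list[HostSpec],
    phages: list[PhageSpec],
    params: ModelParams,
) -> CommunityState:
    """Time derivative of a community state under the chosen model.

    Pure function of its inputs; raises on dimension mismatch or negative
    abundances.  Returned object holds dN/dt, dB_i/dt, dP_j/dt in the
    ``N``/``B``/``P`` slots (and the input time in ``t``).
    """
    model = CompiledModel(kind, hosts, phages, params)
    state.validate(model.n_hosts, model.n_phages)
    dy = model.rhs(state.t, state.to_vector())
    return CommunityState.from_vector(dy, model.n_hosts, t=state.t)


def viral_persistence_threshold(params: ModelParams, host: HostSpec) -> float:
    """Minimum supply rate ``S_crit`` at which phage persist on a lone host.

    Below S_crit the host equilibrium abundance S/delta_b is too small to
    sustain phage replication: S_crit = delta_b * delta_p / (beta * phi * gamma).
    """
    gamma = gamma_coefficient(host.rm_set, params.r_e)
    return params.delta_b * params.delta_p / (params.beta * params.phi * gamma)


def analytic_equilibria(
    params: ModelParams, host: HostSpec, with_virus: bool = False
) -> CommunityState:
    """Closed-form single-host equilibrium, with or without phage.

    Virus-free: N* = delta_b / (alpha (1-c)), B* = S / delta_b, P* = 0.
    With virus: B* = delta_p / (beta phi gamma), N* = S / (alpha (1-c) B*),
    P* = (alpha (1-c) N* - delta_b) / (phi gamma).  The virus can only
    persist when S exceeds :func:`viral_persistence_threshold`; requesting
    the viral equilibrium below that supply raises ``ValueError``.
    """
    au = (host.alpha if host.alpha is not None else params.alpha) * (1.0 - host.cost())
    gamma = gamma_coefficient(host.rm_set, params.r_e)
    if not with_virus:
        return CommunityState(
            N=params.delta_b / au, B=np.array([params.S / params.delta_b]), P=np.array([0.0])
        )
    s_crit = viral_persistence_threshold(params, host)
    if params.S < s_crit:
        raise ValueError(
            f"virus not sustainable: S={params.S:g} below S_crit={s_crit:g}"
        )
    B = params.delta_p / (params.beta * params.phi * gamma)
    N = params.S / (au * B)
    P = (au * N - params.delta_b) / (params.phi * gamma)
    return CommunityState(N=N, B=np.array([B]), P=np.array([P]))
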