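"""Network structure for core/peripheral gene regulatory models.

The model distinguishes a small *core* set of transcription factors, whose
mutual regulation (including feedback loops) is modeled jointly, from
*peripheral* genes that are regulated by core genes only: peripheral genes
never feed back onto the core and never regulate each other.  All candidate
regulations come from a prior edge list; inference activates or removes
edges but never invents edges outside the prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


class StructureError(ValueError):
    """Raised when a network structure violates the core/peripheral contract."""


@dataclass(frozen=True)
class NetworkStructure:
    """Directed regulatory structure over core and peripheral genes.

    Parameters
    ----------
    core_genes : tuple of str
        Ordered identifiers of the core transcription factors.
    peripheral_genes : tuple of str
        Ordered identifiers of all non-core genes; disjoint from the core.
    allowed_edges : tuple of (regulator, target)
        The prior: every edge a model may ever contain.  Regulators must be
        core genes.  Order is canonical and defines the edge index used for
        deterministic tie-breaking during pruning.
    active_edges : frozenset of (regulator, target)
        The edges currently carrying a regulation weight; subset of
        ``allowed_edges``.
    """

    core_genes: tuple[str, ...]
    peripheral_genes: tuple[str, ...] = ()
    allowed_edges: tuple[Edge, ...] = ()
    active_edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        core = set(self.core_genes)
        peri = set(self.peripheral_genes)
        if len(core) != len(self.core_genes):
            raise StructureError("duplicate core gene identifiers")
        if len(peri) != len(self.peripheral_genes):
            raise StructureError("duplicate peripheral gene identifiers")
        if core & peri:
            raise StructureError(
                f"core and peripheral gene lists overlap: {sorted(core & peri)}"
            )
        seen = set()
        for reg, tgt in self.allowed_edges:
            if reg not in core:
                raise StructureError(
                    f"edge {reg}->{tgt}: regulator {reg!r} is not a core gene"
                )
            if tgt not in core and tgt not in peri:
                raise StructureError(
                    f"edge {reg}->{tgt}: target {tgt!r} is not a modeled gene"
                )
            if (reg, tgt) in seen:
                raise StructureError(f"duplicate edge {reg}->{tgt} in allowed_edges")
            seen.add((reg, tgt))
        if not frozenset(self.active_edges) <= seen:
            extra = sorted(frozenset(self.active_edges) - seen)
            raise StructureError(f"active edges outside the prior: {extra}")
        # normalize to frozenset (callers may pass any iterable)
        object.__setattr__(self, "active_edges", frozenset(self.active_edges))

    # -- indexing ---------------------------------------------------------

    @property
    def genes(self) -> tuple[str, ...]:
        """All modeled genes, core first then peripheral (canonical order)."""
        return self.core_genes + self.peripheral_genes

    @property
    def n_genes(self) -> int:
        return len(self.core_genes) + len(self.peripheral_genes)

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    @property
    def edge_index(self) -> dict[Edge, int]:
        """Position of each allowed edge in the canonical prior order."""
        return {e: i for i, e in enumerate(self.allowed_edges)}

    # -- views ------------------------------------------------------------

    @property
    def core_allowed_edges(self) -> tuple[Edge, ...]:
        core = set(self.core_genes)
        return tuple(e for e in self.allowed_edges if e[1] in core)

    @property
    def peripheral_allowed_edges(self) -> tuple[Edge, ...]:
        core = set(self.core_genes)
        return tuple(e for e in self.allowed_edges if e[1] not in core)

    def active_in_edges(self, gene: str) -> tuple[Edge, ...]:
        return tuple(
            e for e in self.allowed_edges if e[1] == gene and e in self.active_edges
        )

    def allowed_in_edges(self, gene: str) -> tuple[Edge, ...]:
        return tuple(e for e in self.allowed_edges if e[1] == gene)

    def core_subsystem(self) -> "NetworkStructure":
        """Restriction to core genes and core->core edges (Step-1 system)."""
        core = set(self.core_genes)
        allowed = self.core_allowed_edges
        active = frozenset(e for e in self.active_edges if e[1] in core)
        return NetworkStructure(self.core_genes, (), allowed, active)

    def with_active(self, active_edges) -> "NetworkStructure":
        return NetworkStructure(
            self.core_genes, self.peripheral_genes, self.allowed_edges,
            frozenset(active_edges),
        )

    def deactivate(self, edge: Edge) -> "NetworkStructure":
        if edge not in self.active_edges:
            raise StructureError(f"edge {edge[0]}->{edge[1]} is not active")
        return self.with_active(self.active_edges - {edge})


def build_structure(prior_edges, core_genes, all_genes) -> NetworkStructure:
    """Assemble a :class:`NetworkStructure` from a prior edge list.

    Prior edges whose regulator is not a core gene are rejected (the model
    class has no mechanism for peripheral regulators).  Duplicate edges are
    collapsed with a warning.  All prior edges start out active.

    Parameters
    ----------
    prior_edges : iterable of (regulator, target)
        Putative regulations, e.g. from TF-binding predictions.
    core_genes : iterable of str
    all_genes : iterable of str
        Complete modeled gene universe; must contain the core genes.
    """
    core_genes = tuple(core_genes)
    all_genes = tuple(all_genes)
    core = set(core_genes)
    universe = set(all_genes)
    if not core <= universe:
        raise StructureError(
            f"core genes missing from gene universe: {sorted(core - universe)}"
        )
    peripheral = tuple(g for g in all_genes if g not in core)

    edges: list[Edge] = []
    seen: set[Edge] = set()
    n_dup = 0
    for reg, tgt in prior_edges:
        e = (str(reg), str(tgt))
        if e[0] not in core:
            raise StructureError(
                f"prior edge {e[0]}->{e[1]}: regulator {e[0]!r} is not a core gene"
            )
        if e[1] not in universe:
            raise StructureError(
                f"prior edge {e[0]}->{e[1]}: target {e[1]!r} not in gene universe"
            )
        if e in seen:
            n_dup += 1
            continue
        seen.add(e)
        edges.append(e)
    if n_dup:
        logger.warning("deduplicated %d repeated prior edges", n_dup)
    return NetworkStructure(
        core_genes=core_genes,
        peripheral_genes=peripheral,
        allowed_edges=tuple(edges),
        active_edges=frozenset(edges),
    )
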