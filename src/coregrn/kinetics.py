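"""Kinetic parameterization and right-hand-side functions.

Default kinetics: sigmoid transcription with linear first-order decay,

    dx_i/dt = -lambda_i * x_i + xi_i / (1 + exp(-sum_j w_ij x_j)),

where ``lambda_i`` is the degradation rate (1/h), ``xi_i`` the maximal
production rate, and ``w_ij`` signed regulation weights over the active
in-edges of gene i.  The production term is confined to (0, xi_i) for any
finite input, so with positive rates every trajectory is bounded.  A linear
alternative ``-lambda_i x_i + sum_j w_ij x_j + xi_i`` (with ``xi_i`` acting
as basal production) and user-supplied forms are also supported.

Search-box bounds: lambda, xi in [0, 20]; w in [-20, 20].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.special import expit

from .network import NetworkStructure

LAMBDA_BOUNDS = (0.0, 20.0)
XI_BOUNDS = (0.0, 20.0)
W_BOUNDS = (-20.0, 20.0)


@dataclass
class KineticParameters:
    """Per-gene rates and per-edge weights for a structure.

    ``genes`` fixes the order of ``lambda_`` and ``xi``.  ``w`` holds one
    entry per *active* edge keyed by (regulator, target); inactive edges
    carry no parameter at all.
    """

    genes: tuple[str, ...]
    lambda_: np.ndarray
    xi: np.ndarray
    w: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lambda_ = np.asarray(self.lambda_, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        if self.lambda_.shape != (len(self.genes),):
            raise ValueError("lambda_ must have one entry per gene")
        if self.xi.shape != (len(self.genes),):
            raise ValueError("xi must have one entry per gene")

    def validate(self, structure: NetworkStructure | None = None) -> None:
        """Check box bounds and, if given, consistency with a structure."""
        if np.any(self.lambda_ < LAMBDA_BOUNDS[0]) or np.any(self.lambda_ > LAMBDA_BOUNDS[1]):
            raise ValueError(f"lambda outside {LAMBDA_BOUNDS}")
        if np.any(self.xi < XI_BOUNDS[0]) or np.any(self.xi > XI_BOUNDS[1]):
            raise ValueError(f"xi outside {XI_BOUNDS}")
        for e, v in self.w.items():
            if not W_BOUNDS[0] <= v <= W_BOUNDS[1]:
                raise ValueError(f"w[{e[0]}->{e[1]}]={v} outside {W_BOUNDS}")
        if structure is not None:
            if tuple(structure.genes) != tuple(self.genes):
                raise ValueError("parameter gene order does not match structure")
            active = set(structure.active_edges)
            keys = set(self.w)
            if keys != active:
                missing = active - keys
                extra = keys - active
                raise ValueError(
                    f"edge weights inconsistent with active edges "
                    f"(missing {sorted(missing)}, extra {sorted(extra)})"
                )

    def w_matrix(self, structure: NetworkStructure) -> np.ndarray:
        """Dense weight matrix W with W[target, regulator] = w_ij."""
        idx = structure.gene_index
        W = np.zeros((structure.n_genes, structure.n_genes))
        for (reg, tgt), v in self.w.items():
            W[idx[tgt], idx[reg]] = v
        return W

    def rate(self, gene: str) -> tuple[float, float]:
        i = self.genes.index(gene)
        return float(self.lambda_[i]), float(self.xi[i])

    def copy(self) -> "KineticParameters":
        return replace(
            self, lambda_=self.lambda_.copy(), xi=self.xi.copy(), w=dict(self.w)
        )


# -- kinetics forms -------------------------------------------------------


@dataclass(frozen=True)
class KineticsForm:
    """A named right-hand-side contract.

    ``production(u, xi)`` maps the summed regulatory input ``u = W x`` and
    the rate ``xi`` to the production term; decay ``-lambda x`` is always
    separate.  This split is what the fast exponential integrator and the
    pruning machinery rely on.
    """

    name: str
    production: Callable[[np.ndarray, np.ndarray], np.ndarray]


def _sigmoid_production(u, xi):
    return xi * expit(u)


def _linear_production(u, xi):
    # xi acts as an additive basal production in the linear form
    return u + xi


SIGMOID = KineticsForm("sigmoid", _sigmoid_production)
LINEAR = KineticsForm("linear", _linear_production)

_FORMS = {"sigmoid": SIGMOID, "linear": LINEAR}


def get_kinetics(form) -> KineticsForm:
    """Resolve a kinetics form from a name or pass a user form through."""
    if isinstance(form, KineticsForm):
        return form
    try:
        return _FORMS[form]
    except KeyError:
        raise ValueError(
            f"unknown kinetics {form!r}; use 'sigmoid', 'linear' or a KineticsForm"
        ) from None


def rhs(
    x: np.ndarray,
    params: KineticParameters,
    structure: NetworkStructure,
    kinetics: KineticsForm | str = SIGMOID,
) -> np.ndarray:
    """Time derivative dx/dt for the full system at state ``x``.

    Raises on dimension mismatch or non-finite state entries.
    """
    kinetics = get_kinetics(kinetics)
    x = np.asarray(x, dtype=float)
    if x.shape != (structure.n_genes,):
        raise ValueError(
            f"state has shape {x.shape}, expected ({structure.n_genes},)"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state entries")
    W = params.w_matrix(structure)
    u = W @ x
    return -params.lambda_ * x + kinetics.production(u, params.xi)
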