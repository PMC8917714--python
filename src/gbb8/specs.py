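"""Factor-model specifications, identification and constraint templates.

Three confirmatory structures are supported for a p-item instrument whose
items load one-per-item on K first-order factors:

* ``one_factor`` — all items on a single factor;
* ``correlated`` — K freely correlated first-order factors;
* ``second_order`` — the K factors load on one second-order factor
  (general somatic symptom burden for the GBB-8).

Identification uses the marker-variable scheme: the first item of each
factor has its loading fixed at 1, the first first-order factor is the
marker of the second-order factor, and latent means are identified by
fixing the reference group's second-order mean to 0. Mean structure is
always estimated (item intercepts free unless constrained); with free
intercepts this is equivalent to a covariance-only fit and leaves the
chi-square and df unchanged.

Multi-group measurement-invariance levels for the second-order structure
follow the usual first/second-order ladder; each level adds constraints on
top of the previous one:

========== ==========================================================
level       constraints (G groups, reference group first)
========== ==========================================================
configural  same pattern, all measurement parameters free per group
weak1       first-order loadings equal
weak2       + second-order loadings equal
strong1     + item intercepts equal; first-order intercepts freed in
            non-reference groups
strong2     + first-order intercepts equal (at 0); second-order latent
            mean freed in non-reference groups
strict1     + item residual variances equal
strict2     + first-order disturbance variances equal
means       + second-order latent means equal (all 0)
========== ==========================================================

The free-parameter count, moment count and df of any specification are
computable without data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import instrument

KINDS = ("one_factor", "correlated", "second_order")

LADDER_LEVELS = (
    "configural", "weak1", "weak2", "strong1",
    "strong2", "strict1", "strict2", "means",
)

LEVEL_LABELS = {
    "configural": "Configural model",
    "weak1": "1st order weak invariance",
    "weak2": "2nd order weak invariance",
    "strong1": "1st order strong invariance",
    "strong2": "2nd order strong invariance",
    "strict1": "1st order strict invariance",
    "strict2": "2nd order strict invariance",
    "means": "Mean equivalence",
}

# tag vocabulary: "free" (per group), "equal" (shared across groups),
# "zero" (fixed at 0 everywhere), "free_nonref" (0 in the reference group,
# free elsewhere)
_SECOND_ORDER_LEVEL_TAGS = {
    "configural": {},
    "weak1": {"loading": "equal"},
    "weak2": {"loading": "equal", "lambda2": "equal"},
    "strong1": {"loading": "equal", "lambda2": "equal", "nu": "equal",
                "tau": "free_nonref"},
    "strong2": {"loading": "equal", "lambda2": "equal", "nu": "equal",
                "alpha": "free_nonref"},
    "strict1": {"loading": "equal", "lambda2": "equal", "nu": "equal",
                "alpha": "free_nonref", "theta": "equal"},
    "strict2": {"loading": "equal", "lambda2": "equal", "nu": "equal",
                "alpha": "free_nonref", "theta": "equal", "psi_d": "equal"},
    "means": {"loading": "equal", "lambda2": "equal", "nu": "equal",
              "theta": "equal", "psi_d": "equal"},
}


class SpecError(ValueError):
    """Raised for inconsistent model specifications."""


@dataclass
class FactorModelSpec:
    """A constraint-tagged CFA specification (data-free)."""

    kind: str
    groups: tuple[str, ...] = ("all",)
    level: str | None = None
    item_names: tuple[str, ...] = instrument.ITEM_NAMES
    subscales: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(instrument.SUBSCALES)
    )
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SpecError(f"unknown structure kind {self.kind!r}")
        if self.level is not None and self.level not in LADDER_LEVELS:
            raise SpecError(f"unknown invariance level {self.level!r}")
        if self.level not in (None, "configural") and self.kind != "second_order":
            raise SpecError(
                "invariance ladder levels beyond configural are defined for "
                "the second-order structure only"
            )
        if self.level is not None and len(self.groups) < 2:
            raise SpecError("invariance levels require at least 2 groups")

    # ------------------------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.item_names)

    @property
    def n_factors(self) -> int:
        return 1 if self.kind == "one_factor" else len(self.subscales)

    @property
    def factor_names(self) -> tuple[str, ...]:
        if self.kind == "one_factor":
            return ("general",)
        return tuple(self.subscales)

    @property
    def factor_of_item(self) -> np.ndarray:
        """First-order factor index per item."""
        if self.kind == "one_factor":
            return np.zeros(self.p, dtype=int)
        lookup = {}
        for j, f in enumerate(self.subscales):
            for it in self.subscales[f]:
                lookup[it] = j
        return np.array([lookup[i] for i in self.item_names])

    @property
    def marker_items(self) -> np.ndarray:
        """Item index fixed at loading 1 for each factor (first listed)."""
        fac = self.factor_of_item
        return np.array([int(np.argmin(fac != j)) for j in range(self.n_factors)])

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def tag(self, cls: str) -> str:
        defaults = {"loading": "free", "nu": "free", "theta": "free",
                    "lambda2": "free", "psi_d": "free", "phi": "free",
                    "psi_diag": "free", "psi_off": "free",
                    "alpha": "zero", "tau": "zero"}
        return self.tags.get(cls, defaults[cls])

    # ------------------------------------------------------------------
    def n_moments(self) -> int:
        p = self.p
        return self.n_groups * (p + p * (p + 1) // 2)

    def n_free_parameters(self) -> int:
        return build_template(self).nfree

    def df(self) -> int:
        return self.n_moments() - self.n_free_parameters()

    def label(self) -> str:
        if self.level is not None:
            return LEVEL_LABELS[self.level]
        return {"one_factor": "One-factor model",
                "correlated": "Correlated four-factor model",
                "second_order": "Second-order model"}[self.kind]


def build_model(
    kind: str,
    groups: tuple[str, ...] | list[str] = ("all",),
    invariance_level: str | None = None,
    item_names: tuple[str, ...] = instrument.ITEM_NAMES,
    subscales: dict[str, tuple[str, str]] | None = None,
) -> FactorModelSpec:
    """Build a constraint-tagged :class:`FactorModelSpec`.

    For ``invariance_level`` in the second-order ladder the appropriate
    cross-group equality tags are applied; the free-parameter count and df
    are then available without data via :meth:`FactorModelSpec.df`.
    """
    groups = tuple(groups)
    tags: dict[str, str] = {}
    if invariance_level is not None:
        if kind != "second_order" and invariance_level != "configural":
            raise SpecError(
                "higher invariance levels require the second-order structure"
            )
        if kind == "second_order":
            tags = dict(_SECOND_ORDER_LEVEL_TAGS[invariance_level])
    return FactorModelSpec(
        kind=kind,
        groups=groups,
        level=invariance_level,
        item_names=tuple(item_names),
        subscales=dict(subscales) if subscales else dict(instrument.SUBSCALES),
        tags=tags,
    )


# ======================================================================
# Parameter template: maps a flat free vector onto per-group natural
# parameter arrays, honouring fixed values and cross-group equalities.
# Variance-type parameters are carried on the log scale in the free vector
# (implicit positivity; a boundary estimate shows up as a very negative
# log value and is reported as a Heywood warning upstream).
# ======================================================================

_LOG_CLASSES = {"theta", "psi_d", "phi", "psi_diag"}


@dataclass
class _Slot:
    idx: np.ndarray     # free-vector index per element, -1 = fixed
    fixed: np.ndarray   # fixed values (used where idx == -1), natural scale


class ParamTemplate:
    """Index map between the flat free vector and structured parameters."""

    def __init__(self, spec: FactorModelSpec):
        self.spec = spec
        self.slots: list[dict[str, _Slot]] = []  # one dict per group
        self._counter = 0
        self._build()

    # -- construction --------------------------------------------------
    def _alloc(self, n: int) -> np.ndarray:
        idx = np.arange(self._counter, self._counter + n)
        self._counter += n
        return idx

    def _build(self) -> None:
        spec = self.spec
        p, K = spec.p, spec.n_factors
        fac = spec.factor_of_item
        markers = spec.marker_items
        for gi, _g in enumerate(spec.groups):
            slots: dict[str, _Slot] = {}

            def shared(cls: str, shape: int, fixed_mask, fixed_vals) -> _Slot:
                """Allocate or share indices according to the class tag."""
                tag = spec.tag(cls)
                fixed_mask = np.asarray(fixed_mask, dtype=bool)
                idx = np.full(shape, -1, dtype=int)
                if tag == "equal" and gi > 0:
                    idx = self.slots[0][cls].idx.copy()
                elif tag in ("free", "equal"):
                    nfree = int((~fixed_mask).sum())
                    idx[~fixed_mask] = self._alloc(nfree)
                elif tag == "free_nonref":
                    if gi > 0:
                        idx[~fixed_mask] = self._alloc(int((~fixed_mask).sum()))
                elif tag == "zero":
                    pass
                else:  # pragma: no cover
                    raise SpecError(f"unknown tag {tag!r} for {cls}")
                return _Slot(idx=idx, fixed=np.asarray(fixed_vals, dtype=float))

            # first-order loadings: markers fixed at 1
            marker_mask = np.zeros(p, dtype=bool)
            marker_mask[markers] = True
            slots["loading"] = shared("loading", p, marker_mask, marker_mask.astype(float))
            # item intercepts, residual variances (log)
            slots["nu"] = shared("nu", p, np.zeros(p, bool), np.zeros(p))
            slots["theta"] = shared("theta", p, np.zeros(p, bool), np.ones(p))

            if spec.kind == "second_order":
                l2_mask = np.zeros(K, dtype=bool)
                l2_mask[0] = True
                slots["lambda2"] = shared("lambda2", K, l2_mask, l2_mask.astype(float))
                slots["psi_d"] = shared("psi_d", K, np.zeros(K, bool), np.ones(K))
                slots["phi"] = shared("phi", 1, np.zeros(1, bool), np.ones(1))
                slots["tau"] = shared("tau", K, np.zeros(K, bool), np.zeros(K))
                slots["alpha"] = shared("alpha", 1, np.zeros(1, bool), np.zeros(1))
            else:
                slots["psi_diag"] = shared("psi_diag", K, np.zeros(K, bool), np.ones(K))
                noff = K * (K - 1) // 2
                slots["psi_off"] = shared("psi_off", noff, np.zeros(noff, bool),
                                          np.zeros(noff))
            self.slots.append(slots)

    @property
    def nfree(self) -> int:
        return self._counter

    # -- packing / unpacking -------------------------------------------
    def unpack(self, x: np.ndarray) -> list[dict[str, np.ndarray]]:
        """Flat free vector -> per-group natural-scale parameter arrays."""
        out = []
        for slots in self.slots:
            g: dict[str, np.ndarray] = {}
            for cls, slot in slots.items():
                vals = slot.fixed.copy()
                m = slot.idx >= 0
                if m.any():
                    raw = x[slot.idx[m]]
                    vals[m] = np.exp(raw) if cls in _LOG_CLASSES else raw
                g[cls] = vals
            out.append(g)
        return out

    def pack(self, params: list[dict[str, np.ndarray]]) -> np.ndarray:
        """Per-group natural parameters -> flat free vector (shared slots
        take the last group's value; identical for admissible inputs)."""
        x = np.zeros(self.nfree)
        for slots, g in zip(self.slots, params):
            for cls, slot in slots.items():
                m = slot.idx >= 0
                if m.any():
                    vals = np.asarray(g[cls], dtype=float)[m]
                    x[slot.idx[m]] = np.log(vals) if cls in _LOG_CLASSES else vals
        return x

    def scatter_grad(
        self, grads: list[dict[str, np.ndarray]], params: list[dict[str, np.ndarray]]
    ) -> np.ndarray:
        """Accumulate per-group natural-scale gradients into the free vector,
        applying the log-scale chain rule for variance classes."""
        out = np.zeros(self.nfree)
        for slots, g, p in zip(self.slots, grads, params):
            for cls, slot in slots.items():
                m = slot.idx >= 0
                if not m.any():
                    continue
                grad = np.asarray(g[cls], dtype=float)[m]
                if cls in _LOG_CLASSES:
                    grad = grad * np.asarray(p[cls], dtype=float)[m]
                np.add.at(out, slot.idx[m], grad)
        return out


def build_template(spec: FactorModelSpec) -> ParamTemplate:
    return ParamTemplate(spec)


def implied_moments(
    spec: FactorModelSpec, g: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance for one group's parameters."""
    fac = spec.factor_of_item
    lam1 = g["loading"]
    if spec.kind == "second_order":
        l2 = g["lambda2"]
        phi = g["phi"][0]
        B = np.outer(l2, l2) * phi + np.diag(g["psi_d"])
        kappa = g["tau"] + l2 * g["alpha"][0]
    else:
        K = spec.n_factors
        B = np.diag(g["psi_diag"]).astype(float)
        iu = np.triu_indices(K, 1)
        B[iu] = g["psi_off"]
        B = B + np.triu(B, 1).T
        kappa = np.zeros(K)
    Sigma = np.outer(lam1, lam1) * B[np.ix_(fac, fac)]
    Sigma[np.diag_indices_from(Sigma)] += g["theta"]
    mu = g["nu"] + lam1 * kappa[fac]
    return mu, Sigma
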