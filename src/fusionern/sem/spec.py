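"""Declarative specification of mean-and-covariance structure models.

A model is described by the LISREL-style ("all-y") matrices

    mu    = nu + Lambda (I - B)^{-1} alpha
    Sigma = Lambda (I - B)^{-1} Psi (I - B)^{-T} Lambda^T + Theta

where ``Lambda`` holds loadings of observed variables on latent variables,
``B`` the structural paths among latents, ``Psi`` latent (co)variances,
``Theta`` observed residual (co)variances, ``nu`` observed intercepts and
``alpha`` latent intercepts/means.  Every matrix cell is either fixed at a
value, free, or constrained equal to other cells through a shared label.

Observed variables that play a structural role (predictors in a path model)
are promoted to "phantom" latents: a latent with the same name, a fixed unit
loading and a zero residual variance, so that all structural algebra lives in
``B`` and ``Psi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["SEMSpec", "CompiledSpec", "ModelSpecificationError"]


class ModelSpecificationError(ValueError):
    """Raised for malformed or non-identified model specifications."""


@dataclass
class _Entry:
    matrix: str  # lam | beta | psi | theta | nu | alpha
    row: str
    col: Optional[str]
    free: bool
    value: float  # fixed value when not free
    label: Optional[str] = None
    start: Optional[float] = None


@dataclass
class CompiledSpec:
    """Index structure produced by :meth:`SEMSpec.compile`."""

    observed: list
    latent: list
    n_free: int
    # per matrix: (base array, rows-idx, cols-idx, theta-idx) for free entries
    base: dict
    free_idx: dict
    # free-parameter metadata, one row per distinct theta index
    param_names: list
    starts: np.ndarray  # may contain nan where no start was given
    entries: list = field(default_factory=list)
    variance_param: Optional[np.ndarray] = None  # bool, >= 0 constrained

    def build(self, theta: np.ndarray) -> dict:
        """Materialize the six parameter matrices for a parameter vector."""
        mats = {}
        for mat, arr in self.base.items():
            out = arr.copy()
            rows, cols, tidx = self.free_idx[mat]
            if len(tidx):
                if cols is None:
                    out[rows] = theta[tidx]
                else:
                    out[rows, cols] = theta[tidx]
            mats[mat] = out
        return mats

    def contract(self, grads: dict) -> np.ndarray:
        """Collapse per-matrix gradients onto the free-parameter vector.

        Symmetric off-diagonal entries are stored twice (at ij and ji) with a
        shared index, so both halves accumulate automatically.
        """
        g = np.zeros(self.n_free)
        for mat, gm in grads.items():
            rows, cols, tidx = self.free_idx[mat]
            if len(tidx) == 0:
                continue
            vals = gm[rows] if cols is None else gm[rows, cols]
            np.add.at(g, tidx, vals)
        return g


class SEMSpec:
    def __init__(self):
        self.observed: list[str] = []
        self.latent: list[str] = []
        self._entries: dict[tuple, _Entry] = {}

    # -- variable declaration ------------------------------------------------
    def add_observed(self, *names: str) -> "SEMSpec":
        for n in names:
            if n in self.observed:
                raise ModelSpecificationError(f"duplicate observed variable {n!r}")
            self.observed.append(n)
        return self

    def add_latent(self, *names: str) -> "SEMSpec":
        for n in names:
            if n in self.latent:
                raise ModelSpecificationError(f"duplicate latent variable {n!r}")
            self.latent.append(n)
        return self

    # -- parameter declaration ----------------------------------------------
    def _set(self, matrix, row, col, free, value, label, start):
        if free and value is not None and start is None:
            start = value
        self._entries[(matrix, row, col)] = _Entry(
            matrix, row, col, free, 0.0 if (free or value is None) else float(value),
            label, start,
        )

    def loading(self, obs, lat, *, free=True, value=None, label=None, start=None):
        self._check(obs, self.observed, "observed")
        self._check(lat, self.latent, "latent")
        self._set("lam", obs, lat, free, value, label, start)
        return self

    def path(self, target, source, *, free=True, value=None, label=None, start=None):
        """Structural path ``target <- source`` (both latent)."""
        self._check(target, self.latent, "latent")
        self._check(source, self.latent, "latent")
        self._set("beta", target, source, free, value, label, start)
        return self

    def variance(self, name, *, free=True, value=None, label=None, start=None):
        mat = "psi" if name in self.latent else "theta"
        self._check(name, self.latent if mat == "psi" else self.observed,
                    "latent or observed")
        self._set(mat, name, name, free, value, label, start)
        return self

    def covariance(self, a, b, *, free=True, value=None, label=None, start=None):
        if a in self.latent and b in self.latent:
            mat = "psi"
        elif a in self.observed and b in self.observed:
            mat = "theta"
        else:
            raise ModelSpecificationError(
                f"covariance({a!r}, {b!r}): both must be latent or both observed; "
                "promote observed structural variables with phantom()")
        key = tuple(sorted((a, b)))
        self._set(mat, key[0], key[1], free, value, label, start)
        return self

    def intercept(self, obs, *, free=True, value=None, label=None, start=None):
        self._check(obs, self.observed, "observed")
        self._set("nu", obs, None, free, value, label, start)
        return self

    def mean(self, lat, *, free=True, value=None, label=None, start=None):
        self._check(lat, self.latent, "latent")
        self._set("alpha", lat, None, free, value, label, start)
        return self

    def phantom(self, name, *, mean_free=True, var_start=None, mean_start=None):
        """Promote observed ``name`` to a latent of the same name.

        Fixed unit loading, zero residual; variance (and optionally mean)
        free, so the variable can take part in structural paths and latent
        covariances.
        """
        self._check(name, self.observed, "observed")
        self.add_latent(name)
        self.loading(name, name, free=False, value=1.0)
        self.variance(name, free=True, start=var_start)
        # theta diagonal fixed at zero
        self._set("theta", name, name, False, 0.0, None, None)
        self.intercept(name, free=False, value=0.0)
        if mean_free:
            self.mean(name, free=True, start=mean_start)
        return self

    def _check(self, name, pool, kind):
        if name not in pool:
            raise ModelSpecificationError(f"unknown {kind} variable {name!r}")

    # -- compilation ---------------------------------------------------------
    def compile(self) -> CompiledSpec:
        p, m = len(self.observed), len(self.latent)
        if p == 0:
            raise ModelSpecificationError("no observed variables")
        oi = {n: i for i, n in enumerate(self.observed)}
        li = {n: i for i, n in enumerate(self.latent)}
        shapes = {"lam": (p, m), "beta": (m, m), "psi": (m, m),
                  "theta": (p, p), "nu": (p,), "alpha": (m,)}
        base = {k: np.zeros(s) for k, s in shapes.items()}
        free = {k: ([], [], []) for k in shapes}

        label_idx: dict[str, int] = {}
        param_names: list[str] = []
        starts: list[float] = []
        next_idx = 0

        def theta_index(entry, name):
            nonlocal next_idx
            if entry.label is not None:
                if entry.label in label_idx:
                    k = label_idx[entry.label]
                    if entry.start is not None and np.isnan(starts[k]):
                        starts[k] = entry.start
                    return k
                label_idx[entry.label] = next_idx
            param_names.append(name if entry.label is None
                               else f"{name} ({entry.label})")
            starts.append(np.nan if entry.start is None else float(entry.start))
            k = next_idx
            next_idx += 1
            return k

        def index_of(mat, name):
            return oi[name] if mat in ("theta", "nu") or (
                mat == "lam") else li[name]

        for (mat, a, b), e in self._entries.items():
            if mat in ("nu", "alpha"):
                i = oi[a] if mat == "nu" else li[a]
                if e.free:
                    k = theta_index(e, f"{a}~1")
                    free[mat][0].append(i)
                    free[mat][2].append(k)
                else:
                    base[mat][i] = e.value
                continue
            if mat == "lam":
                i, j = oi[a], li[b]
                sym = False
                nm = f"{b}=~{a}"
            elif mat == "beta":
                i, j = li[a], li[b]
                sym = False
                nm = f"{a}~{b}"
            else:
                idx = oi if mat == "theta" else li
                i, j = idx[a], idx[b]
                sym = i != j
                nm = f"{a}~~{b}"
            if e.free:
                k = theta_index(e, nm)
                free[mat][0].append(i)
                free[mat][1].append(j)
                free[mat][2].append(k)
                if sym:
                    free[mat][0].append(j)
                    free[mat][1].append(i)
                    free[mat][2].append(k)
            else:
                base[mat][i, j] = e.value
                if sym:
                    base[mat][j, i] = e.value

        free_idx = {}
        for mat in shapes:
            rows, cols, tidx = free[mat]
            if mat in ("nu", "alpha"):
                free_idx[mat] = (np.asarray(rows, int), None,
                                 np.asarray(tidx, int))
            else:
                free_idx[mat] = (np.asarray(rows, int), np.asarray(cols, int),
                                 np.asarray(tidx, int))

        # free variance parameters (psi/theta diagonal) are kept >= 0 during
        # optimization; a solution at the boundary is reported as such
        variance_param = np.zeros(next_idx, bool)
        for (mat, a, b), e in self._entries.items():
            if e.free and mat in ("psi", "theta") and a == b:
                idx = oi if mat == "theta" else li
                rows, cols, tidx = free_idx[mat]
                pos = np.where((rows == idx[a]) & (cols == idx[a]))[0]
                if len(pos):
                    variance_param[tidx[pos[0]]] = True

        compiled = CompiledSpec(
            observed=list(self.observed), latent=list(self.latent),
            n_free=next_idx, base=base, free_idx=free_idx,
            param_names=param_names, starts=np.asarray(starts, float),
            entries=list(self._entries.values()),
            variance_param=variance_param,
        )
        self._validate(compiled)
        return compiled

    def _validate(self, c: CompiledSpec):
        # every latent needs a scale: a fixed loading/path into it, or a fixed variance
        li = {n: i for i, n in enumerate(self.latent)}
        fixed_lam = {j for (mat, a, b), e in self._entries.items()
                     if mat == "lam" and not e.free and e.value != 0
                     for j in [li[b]]}
        fixed_psi = {li[a] for (mat, a, b), e in self._entries.items()
                     if mat == "psi" and a == b and not e.free}
        scaled = fixed_lam | fixed_psi
        # scale propagates along fixed nonzero structural paths, in either
        # direction: a latent tied by a fixed unit path to a scaled latent
        # inherits a metric (e.g. a change factor entering a measured wave-2
        # factor)
        edges = [(li[a], li[b]) for (mat, a, b), e in self._entries.items()
                 if mat == "beta" and not e.free and e.value != 0]
        changed = True
        while changed:
            changed = False
            for tgt, src in edges:
                for u, w in ((tgt, src), (src, tgt)):
                    if u in scaled and w not in scaled:
                        scaled.add(w)
                        changed = True
        for name, j in li.items():
            if j not in scaled:
                raise ModelSpecificationError(
                    f"latent {name!r} has no scale (needs a fixed loading or "
                    "fixed variance)")
        # acyclic / invertible structural part at base values
        beta = c.base["beta"].copy()
        rows, cols, tidx = c.free_idx["beta"]
        # free paths could take any value; require structural invertibility of
        # I - B for generic values: check that latents can be topologically
        # ordered treating any (fixed nonzero or free) path as an edge.
        adj = (beta != 0).astype(int)
        if len(tidx):
            adj[rows, cols] = 1
        n = adj.shape[0]
        indeg = adj.sum(axis=1)
        order = [int(i) for i in np.where(indeg == 0)[0]]
        seen = set(order)
        queue = list(order)
        while queue:
            i = queue.pop()
            for j in np.where(adj[:, i])[0]:
                adj[j, i] = 0
                if adj[j].sum() == 0 and j not in seen:
                    seen.add(int(j))
                    queue.append(int(j))
        if len(seen) != n:
            cyc = [self.latent[i] for i in range(n) if i not in seen]
            raise ModelSpecificationError(
                f"structural cycle among latents {cyc}; (I - B) would be singular")
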