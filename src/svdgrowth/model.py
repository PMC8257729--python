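"""Structural equation model specification in LISREL-style parameter matrices.

A model is described by six parameter matrices over named observed and latent
variables:

* ``Lambda`` — loadings of observed variables on latents,
* ``Beta``   — directed paths among latents,
* ``Psi``    — (residual) covariances among latents,
* ``Theta``  — residual (co)variances of observed variables,
* ``nu``     — observed-variable intercepts,
* ``alpha``  — latent means,

plus probit thresholds ``tau`` for binary observed variables and an optional
``Gamma`` block of direct regressions of observed variables on fully
exogenous observed regressors (e.g. mean-centred age at each wave).

Every entry is either fixed at a value or free with a label; entries sharing
a label share one parameter (equality constraint).  Free variance entries
(diagonals of Psi/Theta) are optimised on the log scale, which keeps them
positive without boundary constraints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

CONTINUOUS = "continuous"
BINARY = "binary"

# matrix identifiers used in the compiled free-parameter map
_LAMBDA, _BETA, _PSI, _THETA, _NU, _ALPHA, _TAU, _GAMMA = range(8)
_MATRIX_NAMES = ["Lambda", "Beta", "Psi", "Theta", "nu", "alpha", "tau", "Gamma"]


@dataclass
class Entry:
    """One parameter-matrix cell: fixed at ``value`` or free starting there."""

    value: float
    free: bool = False
    label: str | None = None

    def to_json(self) -> dict:
        d: dict = {"value": self.value}
        if self.free:
            d["free"] = True
            d["label"] = self.label
        return d

    @staticmethod
    def from_json(d: dict) -> "Entry":
        return Entry(float(d["value"]), bool(d.get("free", False)), d.get("label"))


def fixed(value: float) -> Entry:
    return Entry(float(value), False, None)


def free(label: str, start: float) -> Entry:
    return Entry(float(start), True, label)


class ModelSpecError(ValueError):
    pass


class ModelSpec:
    """Name-keyed SEM specification.

    Parameters
    ----------
    observed : list of (name, kind) or names
        Observed variables in order; kind is ``"continuous"`` or ``"binary"``.
    latents : list of str
        Latent variables in order.
    exog : list of str, optional
        Names of observed exogenous regressor columns entering via ``Gamma``.
    """

    def __init__(self, observed, latents, exog=()):
        self.observed: list[str] = []
        self.kinds: dict[str, str] = {}
        self.meta: dict = {}
        for item in observed:
            if isinstance(item, str):
                name, kind = item, CONTINUOUS
            else:
                name, kind = item
            if kind not in (CONTINUOUS, BINARY):
                raise ModelSpecError(f"unknown kind {kind!r} for {name!r}")
            self.observed.append(name)
            self.kinds[name] = kind
        self.latents = list(latents)
        self.exog = list(exog)
        if len(set(self.observed)) != len(self.observed):
            raise ModelSpecError("duplicate observed variable names")
        if len(set(self.latents)) != len(self.latents):
            raise ModelSpecError("duplicate latent variable names")
        self.lambda_: dict[tuple[str, str], Entry] = {}
        self.beta: dict[tuple[str, str], Entry] = {}
        self.psi: dict[tuple[str, str], Entry] = {}
        self.theta: dict[tuple[str, str], Entry] = {}
        self.nu: dict[str, Entry] = {}
        self.alpha: dict[str, Entry] = {}
        self.tau: dict[str, Entry] = {}
        self.gamma: dict[tuple[str, str], Entry] = {}

    # -- setters -----------------------------------------------------------
    def set_loading(self, obs: str, lat: str, entry: Entry) -> None:
        self._check(obs, self.observed, "observed")
        self._check(lat, self.latents, "latent")
        self.lambda_[(obs, lat)] = entry

    def set_path(self, to_lat: str, from_lat: str, entry: Entry) -> None:
        self._check(to_lat, self.latents, "latent")
        self._check(from_lat, self.latents, "latent")
        self.beta[(to_lat, from_lat)] = entry

    def set_psi(self, a: str, b: str, entry: Entry) -> None:
        self._check(a, self.latents, "latent")
        self._check(b, self.latents, "latent")
        self.psi[(a, b)] = entry
        if a != b:
            self.psi[(b, a)] = entry

    def set_theta(self, a: str, b: str, entry: Entry) -> None:
        self._check(a, self.observed, "observed")
        self._check(b, self.observed, "observed")
        self.theta[(a, b)] = entry
        if a != b:
            self.theta[(b, a)] = entry

    def set_intercept(self, obs: str, entry: Entry) -> None:
        self._check(obs, self.observed, "observed")
        self.nu[obs] = entry

    def set_mean(self, lat: str, entry: Entry) -> None:
        self._check(lat, self.latents, "latent")
        self.alpha[lat] = entry

    def set_threshold(self, obs: str, entry: Entry) -> None:
        if self.kinds.get(obs) != BINARY:
            raise ModelSpecError(f"{obs!r} is not binary; thresholds apply to binary vars")
        self.tau[obs] = entry

    def set_exog_path(self, obs: str, exog: str, entry: Entry) -> None:
        self._check(obs, self.observed, "observed")
        if exog not in self.exog:
            raise ModelSpecError(f"unknown exogenous regressor {exog!r}")
        self.gamma[(obs, exog)] = entry

    @staticmethod
    def _check(name, pool, what):
        if name not in pool:
            raise ModelSpecError(f"unknown {what} variable {name!r}")

    # -- queries -----------------------------------------------------------
    @property
    def binary_vars(self) -> list[str]:
        return [v for v in self.observed if self.kinds[v] == BINARY]

    @property
    def continuous_vars(self) -> list[str]:
        return [v for v in self.observed if self.kinds[v] == CONTINUOUS]

    def n_free(self) -> int:
        labels = set()
        for coll in (self.lambda_, self.beta, self.psi, self.theta, self.gamma):
            labels.update(e.label for e in coll.values() if e.free)
        for coll in (self.nu, self.alpha, self.tau):
            labels.update(e.label for e in coll.values() if e.free)
        return len(labels)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check identification conventions and binary-variable constraints.

        Each latent must carry a scale: either some fixed nonzero loading or
        directed path into it from a scaled variable, or a fixed Psi variance.
        Binary observed variables must have residual variance fixed at 1, no
        free intercept, and load on exactly one latent.
        """
        for lat in self.latents:
            fixed_load = any(
                k[1] == lat and not e.free and e.value != 0.0
                for k, e in self.lambda_.items()
            ) or any(
                k[1] == lat and not e.free and e.value != 0.0
                for k, e in self.beta.items()
            )
            fixed_var = (lat, lat) in self.psi and not self.psi[(lat, lat)].free
            if not (fixed_load or fixed_var):
                raise ModelSpecError(
                    f"latent {lat!r} has no scale (needs a fixed loading or fixed variance)"
                )
        for v in self.binary_vars:
            th = self.theta.get((v, v))
            if th is None or th.free or th.value != 1.0:
                raise ModelSpecError(f"binary var {v!r} must have residual variance fixed at 1")
            if v in self.nu and (self.nu[v].free or self.nu[v].value != 0.0):
                raise ModelSpecError(f"binary var {v!r} may not have a free intercept; use tau")
            loads = [k[1] for k, e in self.lambda_.items() if k[0] == v and (e.free or e.value != 0.0)]
            if len(loads) != 1:
                raise ModelSpecError(
                    f"binary var {v!r} must load on exactly one latent (got {loads})"
                )
            if v not in self.tau:
                raise ModelSpecError(f"binary var {v!r} needs a threshold entry")
        if self.binary_vars:
            anchors = {
                [k[1] for k, e in self.lambda_.items() if k[0] == v and (e.free or e.value != 0.0)][0]
                for v in self.binary_vars
            }
            if len(anchors) != 1:
                raise ModelSpecError(
                    "all binary variables must load on the same latent "
                    f"(one-dimensional integration); got {sorted(anchors)}"
                )

    def integration_latent(self) -> str | None:
        """The single latent the binary indicators load on, if any."""
        if not self.binary_vars:
            return None
        v = self.binary_vars[0]
        return [k[1] for k, e in self.lambda_.items() if k[0] == v and (e.free or e.value != 0.0)][0]

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        def enc(d, tupkey):
            if tupkey:
                return [{"row": k[0], "col": k[1], **e.to_json()} for k, e in d.items()]
            return [{"row": k, **e.to_json()} for k, e in d.items()]

        doc = {
            "observed": [[v, self.kinds[v]] for v in self.observed],
            "latents": self.latents,
            "exog": self.exog,
            "meta": self.meta,
            "Lambda": enc(self.lambda_, True),
            "Beta": enc(self.beta, True),
            "Psi": enc(self.psi, True),
            "Theta": enc(self.theta, True),
            "nu": enc(self.nu, False),
            "alpha": enc(self.alpha, False),
            "tau": enc(self.tau, False),
            "Gamma": enc(self.gamma, True),
        }
        return json.dumps(doc, indent=1)

    @staticmethod
    def from_json(text: str) -> "ModelSpec":
        doc = json.loads(text)
        spec = ModelSpec(doc["observed"], doc["latents"], doc.get("exog", ()))
        spec.meta = doc.get("meta", {})
        for key, attr in [("Lambda", "lambda_"), ("Beta", "beta"), ("Psi", "psi"),
                          ("Theta", "theta"), ("Gamma", "gamma")]:
            for item in doc.get(key, []):
                getattr(spec, attr)[(item["row"], item["col"])] = Entry.from_json(item)
        for key, attr in [("nu", "nu"), ("alpha", "alpha"), ("tau", "tau")]:
            for item in doc.get(key, []):
                getattr(spec, attr)[item["row"]] = Entry.from_json(item)
        return spec

    def compile(self) -> "CompiledModel":
        self.validate()
        return CompiledModel(self)


@dataclass
class FreeParam:
    label: str
    log_scale: bool
    # entries: list of (matrix_id, i, j); for vectors j == 0
    entries: list[tuple[int, int, int]] = field(default_factory=list)
    start: float = 0.0


class CompiledModel:
    """Index-based compilation of a :class:`ModelSpec`.

    Holds dense base matrices (fixed values, zeros elsewhere), the map from
    free-parameter labels to matrix cells, and the transform bookkeeping.
    Optimisation operates on the transformed vector ``theta_t`` (log scale for
    variances); :meth:`natural` maps back.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.obs_index = {v: i for i, v in enumerate(spec.observed)}
        self.lat_index = {v: i for i, v in enumerate(spec.latents)}
        self.exog_index = {v: i for i, v in enumerate(spec.exog)}
        self.cont_vars = spec.continuous_vars
        self.bin_vars = spec.binary_vars
        self.cont_rows = np.array([self.obs_index[v] for v in self.cont_vars], dtype=int)
        self.bin_rows = np.array([self.obs_index[v] for v in self.bin_vars], dtype=int)
        p = len(spec.observed)
        m = len(spec.latents)
        q = len(spec.exog)
        self.p, self.m, self.q = p, m, q
        self.int_latent = spec.integration_latent()
        self.int_latent_idx = self.lat_index[self.int_latent] if self.int_latent else -1

        self.base = {
            _LAMBDA: np.zeros((p, m)),
            _BETA: np.zeros((m, m)),
            _PSI: np.zeros((m, m)),
            _THETA: np.zeros((p, p)),
            _NU: np.zeros((p, 1)),
            _ALPHA: np.zeros((m, 1)),
            _TAU: np.zeros((p, 1)),
            _GAMMA: np.zeros((p, max(q, 1))),
        }
        params: dict[str, FreeParam] = {}

        def put(mat_id, i, j, entry: Entry, is_var: bool):
            if entry.free:
                if entry.label is None:
                    raise ModelSpecError("free entry without label")
                fp = params.get(entry.label)
                if fp is None:
                    fp = FreeParam(entry.label, log_scale=is_var, start=entry.value)
                    params[entry.label] = fp
                else:
                    if fp.log_scale != is_var:
                        raise ModelSpecError(
                            f"label {entry.label!r} mixes variance and non-variance entries"
                        )
                fp.entries.append((mat_id, i, j))
            else:
                self.base[mat_id][i, j] = entry.value

        for (o, l), e in spec.lambda_.items():
            put(_LAMBDA, self.obs_index[o], self.lat_index[l], e, False)
        for (a, b), e in spec.beta.items():
            put(_BETA, self.lat_index[a], self.lat_index[b], e, False)
        for (a, b), e in spec.psi.items():
            put(_PSI, self.lat_index[a], self.lat_index[b], e, a == b)
        for (a, b), e in spec.theta.items():
            put(_THETA, self.obs_index[a], self.obs_index[b], e, a == b)
        for o, e in spec.nu.items():
            put(_NU, self.obs_index[o], 0, e, False)
        for l, e in spec.alpha.items():
            put(_ALPHA, self.lat_index[l], 0, e, False)
        for o, e in spec.tau.items():
            put(_TAU, self.obs_index[o], 0, e, False)
        for (o, x), e in spec.gamma.items():
            put(_GAMMA, self.obs_index[o], self.exog_index[x], e, False)

        self.params = list(params.values())
        self.labels = [fp.label for fp in self.params]
        self.n_free = len(self.params)
        # Precompute scatter arrays per matrix for fast fill/gather
        self._scatter: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for mat_id in range(8):
            pidx, ii, jj = [], [], []
            for k, fp in enumerate(self.params):
                for (mid, i, j) in fp.entries:
                    if mid == mat_id:
                        pidx.append(k)
                        ii.append(i)
                        jj.append(j)
            self._scatter[mat_id] = (
                np.array(pidx, dtype=int),
                np.array(ii, dtype=int),
                np.array(jj, dtype=int),
            )
        self.log_scale = np.array([fp.log_scale for fp in self.params], dtype=bool)

    # -- parameter vector transforms --------------------------------------
    def start_vector(self) -> np.ndarray:
        x = np.array([fp.start for fp in self.params], dtype=float)
        return self.transform(x)

    def transform(self, natural: np.ndarray) -> np.ndarray:
        t = np.asarray(natural, dtype=float).copy()
        bad = self.log_scale & (t <= 0)
        if bad.any():
            raise ModelSpecError(
                f"non-positive start for variance parameter(s) {np.array(self.labels)[bad]}"
            )
        t[self.log_scale] = np.log(t[self.log_scale])
        return t

    def natural(self, theta_t: np.ndarray) -> np.ndarray:
        x = np.asarray(theta_t, dtype=float).copy()
        x[self.log_scale] = np.exp(x[self.log_scale])
        return x

    def natural_jacobian_diag(self, theta_t: np.ndarray) -> np.ndarray:
        """d(natural)/d(transformed), elementwise."""
        d = np.ones_like(theta_t)
        d[self.log_scale] = np.exp(theta_t[self.log_scale])
        return d

    def estimates_dict(self, theta_t: np.ndarray) -> dict[str, float]:
        nat = self.natural(theta_t)
        return dict(zip(self.labels, nat.tolist()))

    # -- matrix assembly ---------------------------------------------------
    def matrices(self, theta_t: np.ndarray):
        nat = self.natural(theta_t)
        mats = [self.base[mid].copy() for mid in range(8)]
        for mid in range(8):
            pidx, ii, jj = self._scatter[mid]
            if len(pidx):
                mats[mid][ii, jj] = nat[pidx]
        Lam, B, Psi, Th, nu, alpha, tau, Gam = mats
        return Lam, B, Psi, Th, nu[:, 0], alpha[:, 0], tau[:, 0], Gam

    def gather_grad(self, theta_t: np.ndarray, adjoints: dict[int, np.ndarray]) -> np.ndarray:
        """Sum matrix adjoints into the free-parameter gradient (transformed scale)."""
        g = np.zeros(self.n_free)
        for mid, adj in adjoints.items():
            pidx, ii, jj = self._scatter[mid]
            if len(pidx):
                np.add.at(g, pidx, adj[ii, jj])
        # chain through exp for log-scale parameters
        g *= self.natural_jacobian_diag(theta_t)
        return g
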