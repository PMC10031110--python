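"""Declarative SEM model specification.

A :class:`ModelSpec` describes a covariance-structure model in the familiar
LISREL-style matrices

* ``lambda`` — loadings of observed variables on latent variables,
* ``beta``   — directed paths among latent variables (second-order loadings
  and regressions),
* ``psi``    — (residual) variances and covariances of latent variables,
* ``theta``  — residual variances and covariances of observed variables,
* ``nu``     — observed-variable intercepts (only when a mean structure is
  requested, e.g. for FIML).

Models are written in a small lavaan-like text syntax::

    ADR =~ sDHEA + sT + srADR        # latent measured by (here: latent) indicators
    sDHEA =~ s_dhea_1 + s_dhea_2     # first-order factor over observed columns
    s_dhea_1 ~~ s_t_1                # residual covariance
    ADR ~~ GON                       # latent covariance
    ADR ~ age                        # regression
    sDHEA =~ 0*hair_dhea             # loading fixed to 0

An observed variable used in a structural position (``~`` or ``~~`` with a
latent) is promoted to a *phantom* latent: a latent with a single fixed unit
loading and zero residual variance, whose variance and covariances are free.
This is how exogenous covariates (age) and outcome variables (regional
cortical thickness) enter factor models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = ["ParamCell", "ModelSpec", "parse_model_text"]

_MATRICES = ("lam", "bet", "psi", "tht", "nu")


@dataclass
class ParamCell:
    """One cell of one model matrix: free parameter or fixed value."""

    matrix: str
    row: int
    col: int
    free: bool
    value: float | None  # fixed value, or start value (None = heuristic)
    label: str


def _split_terms(rhs: str) -> list[tuple[float | None, str]]:
    terms = []
    for raw in rhs.split("+"):
        raw = raw.strip()
        if not raw:
            raise ValueError(f"empty term in model line near {rhs!r}")
        if "*" in raw:
            coef_s, name = raw.split("*", 1)
            terms.append((float(coef_s), name.strip()))
        else:
            terms.append((None, raw))
    return terms


def parse_model_text(text: str) -> list[tuple[str, str, float | None, str]]:
    """Parse model syntax into (lhs, op, coef, rhs-variable) tuples."""
    out = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        for op in ("=~", "~~", "~"):
            if op in line:
                lhs, rhs = line.split(op, 1)
                lhs = lhs.strip()
                if not re.fullmatch(r"[A-Za-z_]\w*", lhs):
                    raise ValueError(f"bad variable name {lhs!r}")
                for coef, name in _split_terms(rhs):
                    out.append((lhs, op, coef, name))
                break
        else:
            raise ValueError(f"cannot parse model line: {line!r}")
    return out


class ModelSpec:
    """A structural-equation model specification.

    Parameters
    ----------
    text:
        Model syntax (see module docstring).
    ordinal:
        Mapping from observed variable name to its number of categories;
        such variables are treated as thresholded latent responses by the
        pairwise-likelihood estimator.
    estimator:
        Default estimator tag: ``"ml"``, ``"mlr"``, ``"fiml"`` or ``"pml"``.
    identification:
        ``"unit"`` fixes every non-phantom latent (residual) variance to 1;
        ``"marker"`` instead fixes the first declared loading of each latent
        to 1 and leaves the variance free.
    meanstructure:
        Add free intercepts ``nu`` for every observed variable.
    """

    def __init__(
        self,
        text: str,
        *,
        ordinal: dict[str, int] | None = None,
        estimator: str = "ml",
        identification: str = "unit",
        meanstructure: bool = False,
    ) -> None:
        if identification not in ("unit", "marker"):
            raise ValueError(f"unknown identification rule {identification!r}")
        self.text = text
        self.ordinal = dict(ordinal or {})
        self.estimator = estimator
        self.identification = identification
        self.meanstructure = meanstructure

        edges = parse_model_text(text)
        self._build(edges)

    # ------------------------------------------------------------------
    def _build(self, edges) -> None:
        latents: list[str] = []
        for lhs, op, _, _ in edges:
            if op == "=~" and lhs not in latents:
                latents.append(lhs)
        latset = set(latents)

        observed: list[str] = []

        def see_observed(name: str) -> None:
            if name not in latset and name not in observed:
                observed.append(name)

        for lhs, op, _, rhs in edges:
            if op == "=~":
                see_observed(rhs)
            else:
                see_observed(lhs)
                see_observed(rhs)

        # phantom promotion: observed variables in structural positions
        phantom: list[str] = []

        def promote(name: str) -> None:
            if name in latset or name in phantom:
                return
            phantom.append(name)

        for lhs, op, _, rhs in edges:
            if op == "~":
                promote(lhs)
                promote(rhs)
            elif op == "~~" and lhs != rhs:
                if (lhs in latset) != (rhs in latset):
                    promote(lhs)
                    promote(rhs)

        self.observed = observed
        self.latents = latents + phantom
        self.phantom = set(phantom)
        self._oi = {v: i for i, v in enumerate(self.observed)}
        self._li = {v: i for i, v in enumerate(self.latents)}

        cells: dict[tuple[str, int, int], ParamCell] = {}

        def put(matrix, r, c, free, value, label, override=False):
            key = (matrix, r, c)
            if key in cells and not override:
                raise ValueError(f"duplicate parameter {label!r}")
            cells[key] = ParamCell(matrix, r, c, free, value, label)

        # declared edges
        first_loading_of: dict[str, tuple[str, int, int]] = {}
        for lhs, op, coef, rhs in edges:
            if op == "=~":
                c = self._li[lhs]
                if rhs in latset:
                    put("bet", self._li[rhs], c, coef is None, coef,
                        f"{lhs}=~{rhs}")
                else:
                    put("lam", self._oi[rhs], c, coef is None, coef,
                        f"{lhs}=~{rhs}")
                    if lhs not in first_loading_of and coef is None:
                        first_loading_of[lhs] = ("lam", self._oi[rhs], c)
            elif op == "~":
                put("bet", self._li[lhs], self._li[rhs], coef is None, coef,
                    f"{lhs}~{rhs}")
            else:  # ~~
                both_plain_observed = (
                    lhs not in latset and rhs not in latset
                    and lhs not in self.phantom and rhs not in self.phantom
                )
                if both_plain_observed:
                    r, c = sorted((self._oi[lhs], self._oi[rhs]))
                    put("tht", r, c, coef is None, coef, f"{lhs}~~{rhs}")
                else:
                    r, c = sorted((self._li[lhs], self._li[rhs]))
                    put("psi", r, c, coef is None, coef, f"{lhs}~~{rhs}")

        # phantom machinery: unit loading, zero residual, free variance
        for v in phantom:
            oi, li = self._oi[v], self._li[v]
            put("lam", oi, li, False, 1.0, f"{v}=~{v}(phantom)")
            put("tht", oi, oi, False, 0.0, f"{v}~~{v}(resid)", override=True)
            if ("psi", li, li) not in cells:
                put("psi", li, li, True, None, f"{v}~~{v}")

        # latent (residual) variances per identification rule
        for f in latents:
            li = self._li[f]
            if ("psi", li, li) in cells:
                continue
            if self.identification == "unit":
                put("psi", li, li, False, 1.0, f"{f}~~{f}")
            else:
                put("psi", li, li, True, None, f"{f}~~{f}")
                mk = first_loading_of.get(f)
                if mk is not None:
                    cell = cells[mk]
                    cell.free = False
                    cell.value = 1.0

        # observed residual variances (unless fixed by phantom rule)
        for v in observed:
            oi = self._oi[v]
            if ("tht", oi, oi) not in cells:
                constrained = self.estimator == "pml" and v in self.ordinal
                if constrained:
                    # delta parameterization: total latent-response variance 1
                    put("tht", oi, oi, False, None, f"{v}~~{v}(unit)")
                else:
                    put("tht", oi, oi, True, None, f"{v}~~{v}")

        # intercepts
        if self.meanstructure:
            for v in observed:
                put("nu", self._oi[v], 0, True, None, f"{v}~1")

        self.cells = cells
        order = {m: k for k, m in enumerate(_MATRICES)}
        self.free_cells: list[ParamCell] = sorted(
            (c for c in cells.values() if c.free),
            key=lambda c: (order[c.matrix], c.col, c.row),
        )
        self.labels = [c.label for c in self.free_cells]

    # ------------------------------------------------------------------
    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def n_latent(self) -> int:
        return len(self.latents)

    @property
    def n_free(self) -> int:
        return len(self.free_cells)

    def unit_variance_ordinal(self) -> list[int]:
        """Indices of observed variables whose total variance is constrained
        to 1 (ordinal latent responses under PML)."""
        return [
            self._oi[v]
            for v in self.observed
            if self.estimator == "pml" and v in self.ordinal
        ]

    # ------------------------------------------------------------------
    def start_vector(
        self,
        sample_variances: np.ndarray | None = None,
        sample_means: np.ndarray | None = None,
    ) -> np.ndarray:
        """Heuristic start values.

        Loadings start at 0.7 times the indicator SD, residual variances at
        half the observed variance, latent covariances at 0.3 (0 when a
        phantom is involved), regressions at 0.3, phantom variances at the
        observed variance.
        """
        p = self.n_observed
        v = (
            np.asarray(sample_variances, float)
            if sample_variances is not None
            else np.ones(p)
        )
        mns = (
            np.asarray(sample_means, float)
            if sample_means is not None
            else np.zeros(p)
        )
        phant_idx = {self._li[x] for x in self.phantom}
        start = np.empty(self.n_free)
        for k, c in enumerate(self.free_cells):
            if c.value is not None:
                start[k] = c.value
            elif c.matrix == "lam":
                start[k] = 0.7 * np.sqrt(v[c.row])
            elif c.matrix == "bet":
                start[k] = 0.3
            elif c.matrix == "psi":
                if c.row == c.col:
                    if c.row in phant_idx:
                        lam_row = self._phantom_indicator(c.row)
                        start[k] = v[lam_row]
                    else:
                        start[k] = 1.0
                else:
                    start[k] = (
                        0.0
                        if (c.row in phant_idx or c.col in phant_idx)
                        else 0.3
                    )
            elif c.matrix == "tht":
                start[k] = 0.5 * v[c.row] if c.row == c.col else 0.0
            else:  # nu
                start[k] = mns[c.row]
        return start

    def _phantom_indicator(self, latent_index: int) -> int:
        name = self.latents[latent_index]
        return self._oi[name]

    # ------------------------------------------------------------------
    def matrices(self, theta: np.ndarray):
        """Assemble (lambda, beta, psi, theta_resid, nu) for a parameter
        vector ``theta`` over the free cells."""
        p, m = self.n_observed, self.n_latent
        lam = np.zeros((p, m))
        bet = np.zeros((m, m))
        psi = np.zeros((m, m))
        tht = np.zeros((p, p))
        nu = np.zeros(p)
        mats = {"lam": lam, "bet": bet, "psi": psi, "tht": tht}
        for c in self.cells.values():
            val = 0.0 if c.value is None else c.value
            if c.free:
                continue
            if c.matrix == "nu":
                nu[c.row] = val
            else:
                M = mats[c.matrix]
                M[c.row, c.col] = val
                if c.matrix in ("psi", "tht"):
                    M[c.col, c.row] = val
        for val, c in zip(np.asarray(theta, float), self.free_cells):
            if c.matrix == "nu":
                nu[c.row] = val
            else:
                M = mats[c.matrix]
                M[c.row, c.col] = val
                if c.matrix in ("psi", "tht"):
                    M[c.col, c.row] = val
        # delta-parameterized ordinal residuals: theta_ii = 1 - communality
        uv = self.unit_variance_ordinal()
        if uv:
            ib = np.linalg.inv(np.eye(m) - bet)
            phi = ib @ psi @ ib.T
            comm = np.einsum("ij,jk,ik->i", lam, phi, lam)
            for i in uv:
                tht[i, i] = 1.0 - comm[i]
        return lam, bet, psi, tht, nu

    # ------------------------------------------------------------------
    def to_text(self) -> str:
        """Serialize back to model syntax (one line per declared path)."""
        lines = []
        for (matrix, r, c), cell in sorted(self.cells.items()):
            pre = "" if cell.free else f"{0.0 if cell.value is None else cell.value:g}*"
            if matrix == "lam" and "(phantom)" not in cell.label:
                lines.append(f"{self.latents[c]} =~ {pre}{self.observed[r]}")
            elif matrix == "bet":
                lines.append(f"{self.latents[c]} =~ {pre}{self.latents[r]}"
                             if "=~" in cell.label
                             else f"{self.latents[r]} ~ {pre}{self.latents[c]}")
            elif matrix == "psi" and r != c:
                lines.append(f"{self.latents[r]} ~~ {pre}{self.latents[c]}")
            elif matrix == "tht" and r != c:
                lines.append(f"{self.observed[r]} ~~ {pre}{self.observed[c]}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ModelSpec({self.n_observed} observed, {self.n_latent} latent, "
            f"{self.n_free} free, estimator={self.estimator!r})"
        )
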