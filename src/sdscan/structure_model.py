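"""Initiation-region folding energy and structure residualization.

mRNA secondary structure around the start codon (the -30 ... +30 initiation
region) suppresses translation initiation, and its predicted folding energy
dG_folding correlates strongly with log RTE.  To isolate the contribution of
anti-Shine-Dalgarno complementarity, log RTE is first regressed on
dG_folding by ordinary least squares and all downstream modelling uses the
residuals,

    residual_i = log RTE_i - (a + b * dG_folding,i)

in units of log-scaled translation efficiency.

Two folding engines are provided behind one contract (RNA sequence ->
dG <= 0 kcal/mol, deterministic):

* ``ViennaFoldingEngine`` - minimum free energy folding via the ViennaRNA
  (RNAfold) bindings, when importable.
* ``BuiltinFoldingEngine`` - a dependency-free maximum weighted base-pairing
  dynamic program (pair weights GC = -3, AU = -2, GU = -1 kcal-like units,
  minimum hairpin loop 3).  Its output is a pseudo-dG: it tracks real folding
  energies in rank but not in absolute value, which is sufficient for a
  covariate used only inside a fitted linear term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

# pair pseudo-energies, kcal/mol-like; +inf marks a disallowed pair
_PAIR_WEIGHT = np.full((4, 4), np.inf)
for _a, _b, _w in [("G", "C", -3.0), ("C", "G", -3.0),
                   ("A", "U", -2.0), ("U", "A", -2.0),
                   ("G", "U", -1.0), ("U", "G", -1.0)]:
    _PAIR_WEIGHT[_BASE_INDEX[_a], _BASE_INDEX[_b]] = _w

_MIN_LOOP = 3


def encode_rna(seq: str) -> np.ndarray:
    """RNA string -> int8 array (A=0, C=1, G=2, U=3). N is a ValueError."""
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"cannot fold sequence containing {exc.args[0]!r}") from None


def _nussinov_batch(encoded: np.ndarray) -> np.ndarray:
    """Minimum total pair weight for each row of an (n_seq, L) encoded batch.

    Classic O(L^3) interval DP, vectorized across sequences so that folding
    thousands of 60-mers costs a few thousand numpy operations in total.
    """
    n, L = encoded.shape
    if L < _MIN_LOOP + 2:
        return np.zeros(n)
    # pairw[s, i, j] = weight of pairing base i with base j in sequence s
    pairw = _PAIR_WEIGHT[encoded[:, :, None], encoded[:, None, :]]
    W = np.zeros((L, L, n))
    for span in range(_MIN_LOOP + 1, L):
        for i in range(L - span):
            j = i + span
            best = np.minimum(W[i + 1, j], W[i, j - 1])
            np.minimum(best, W[i + 1, j - 1] + pairw[:, i, j], out=best)
            if span > _MIN_LOOP + 1:
                # bifurcation: split at k, i <= k < j
                split = W[i, i:j, :] + W[i + 1 : j + 1, j, :]
                np.minimum(best, split.min(axis=0), out=best)
            W[i, j] = best
    return W[0, L - 1]


@dataclass(frozen=True)
class BuiltinFoldingEngine:
    """Maximum weighted base-pairing fold; reports a pseudo-dG (<= 0)."""

    name: str = "builtin-maxpair"

    def fold_energy(self, sequence: str) -> float:
        return float(_nussinov_batch(encode_rna(sequence)[None, :])[0])

    def fold_energies(self, sequences: list[str]) -> np.ndarray:
        if not sequences:
            return np.zeros(0)
        lengths = {len(s) for s in sequences}
        if len(lengths) == 1:
            return _nussinov_batch(np.stack([encode_rna(s) for s in sequences]))
        return np.array([self.fold_energy(s) for s in sequences])


@dataclass(frozen=True)
class ViennaFoldingEngine:
    """Minimum-free-energy folding via the ViennaRNA (RNAfold) bindings."""

    name: str = "viennarna-rnafold"

    def fold_energy(self, sequence: str) -> float:
        import RNA  # deferred: optional engine

        encode_rna(sequence)  # reject N and other non-ACGU characters
        _, mfe = RNA.fold(sequence)
        return float(min(0.0, mfe))

    def fold_energies(self, sequences: list[str]) -> np.ndarray:
        return np.array([self.fold_energy(s) for s in sequences])


def get_folding_engine(name: str = "builtin"):
    """``builtin`` | ``viennarna`` | ``auto`` (ViennaRNA if importable)."""
    if name == "builtin":
        return BuiltinFoldingEngine()
    if name == "viennarna":
        return ViennaFoldingEngine()
    if name == "auto":
        try:
            import RNA  # noqa: F401
            return ViennaFoldingEngine()
        except ImportError:
            return BuiltinFoldingEngine()
    raise ValueError(f"unknown folding engine {name!r}")


def fold_energy(engine, sequence: str) -> float:
    """dG_folding (kcal/mol, <= 0) of one RNA sequence under ``engine``."""
    return engine.fold_energy(sequence)


@dataclass(frozen=True)
class ResidualRecord:
    gene_id: str
    dg_fold: float
    log_rte: float
    predicted_log_rte: float
    residual: float


def residualize(records: pd.DataFrame, min_n: int = 10):
    """OLS of log_rte on dg_fold; returns (residual table, fit statistics).

    ``records`` needs columns gene_id, log_rte, dg_fold (finite).  The
    returned table adds predicted_log_rte and residual columns; the stats
    dict carries slope, intercept, r2 and the F-test p-value.  Residuals have
    mean zero by construction (intercept included).
    """
    df = records[["gene_id", "log_rte", "dg_fold"]].dropna().copy()
    n = len(df)
    if n < min_n:
        raise ValueError(f"residualization needs >= {min_n} genes, got {n}")
    x = df["dg_fold"].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite dg_fold values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: dg_fold has zero variance")
    y = df["log_rte"].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    df["predicted_log_rte"] = model.fittedvalues
    df["residual"] = model.resid
    stats = {
        "n": n,
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r2": float(model.rsquared),
        "p_value": float(model.f_pvalue),
    }
    return df, stats
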