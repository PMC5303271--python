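"""aSD::mRNA duplex hybridization energies for upstream windows.

The scan slides a window of the putative anti-Shine-Dalgarno (aSD) sequence
length along the 5' UTR and asks, at each distance d from the start codon,
how stably the aSD would hybridize to that window.  Distance is the number
of bases strictly between the window's 3'-most base and the first base of
the start codon, written as a negative integer: a window of length 5 at
d = -7 occupies UTR positions -12 ... -8.  Measuring from the window's 3'
end keeps d invariant when the aSD definition is extended 5'; the
``core_register_distance`` helper converts to the numbering used when
distances are referenced to the core aSD register.

Two duplex engines share one contract ((aSD RNA, window RNA of equal
length) -> dG_binding <= 0 kcal/mol, deterministic, 0 when no stable duplex
exists):

* ``BuiltinDuplexEngine`` - gapless antiparallel hybridization at the full-
  length register, scored with Turner 2004 nearest-neighbor stacking free
  energies (Watson-Crick and GU wobble) plus a +4.09 kcal/mol duplex
  initiation penalty.  Isolated single pairs contribute no stacking term.
  Because window and aSD have equal length, the fixed register is the
  optimum the scan varies; bulges and internal loops are deliberately not
  modelled.
* ``ViennaCofoldEngine`` - full cofolding via the ViennaRNA (RNAcofold)
  bindings, when importable.  Used as an independent cross-check of the
  built-in ranking, not as a different scoring of the same alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .structure_model import _BASE_INDEX, encode_rna

_INDEX_BASE = "ACGU"

#: complementary (including GU wobble) pair matrix over base indices
_IS_PAIR = np.zeros((4, 4), dtype=bool)
for _a, _b in [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]:
    _IS_PAIR[_BASE_INDEX[_a], _BASE_INDEX[_b]] = True


def _load_stack_table():
    """Packaged Turner 2004 stacking dG37 table -> (4x4x4x4 array, init penalty).

    Entry [a1, b1, a2, b2] is the stacking free energy of consecutive pairs
    a1:b1 and a2:b2 read 5'->3' on the top strand.
    """
    table = np.zeros((4, 4, 4, 4))
    init = 4.09
    text = resources.files("sdscan").joinpath("data/stack_dg37.tsv").read_text()
    for line in text.splitlines():
        if line.startswith("#"):
            if "duplex_initiation" in line:
                init = float(line.split("\t")[1].split()[0])
            continue
        if line.startswith("pair1") or not line.strip():
            continue
        p1, p2, dg = line.split("\t")
        table[_BASE_INDEX[p1[0]], _BASE_INDEX[p1[1]],
              _BASE_INDEX[p2[0]], _BASE_INDEX[p2[1]]] = float(dg)
    return table, init


_STACK_DG37, _INIT_PENALTY = _load_stack_table()


@dataclass(frozen=True)
class BuiltinDuplexEngine:
    """Gapless nearest-neighbor hybridization at the full-length register."""

    name: str = "builtin-nearest-neighbor"
    init_penalty: float = _INIT_PENALTY
    stack_table: np.ndarray = field(default_factory=lambda: _STACK_DG37,
                                    repr=False)

    def duplex_energy(self, asd: str, window: str) -> float:
        if len(asd) != len(window):
            raise ValueError(
                f"length mismatch: aSD {len(asd)} nt vs window {len(window)} nt"
            )
        return float(self.duplex_energies(encode_rna(asd), encode_rna(window)[None, :])[0])

    def duplex_energies(self, asd_idx: np.ndarray, windows: np.ndarray) -> np.ndarray:
        """Vectorized energies for many windows of one aSD.

        ``asd_idx``: (x,) encoded aSD; ``windows``: (n, x) encoded windows.
        The aSD base at position i pairs (antiparallel) with window base
        x-1-i; stacking terms accrue between consecutive paired positions.
        """
        x = asd_idx.shape[0]
        wrev = windows[:, ::-1]  # wrev[:, i] pairs with asd_idx[i]
        paired = _IS_PAIR[asd_idx[None, :], wrev]  # (n, x)
        both = paired[:, :-1] & paired[:, 1:]  # stack between i and i+1
        # stack key: top strand 5'-asd[i] asd[i+1]-3', bottom 3'-w[i] w[i+1]-5'
        stacks = self.stack_table[asd_idx[None, :-1], wrev[:, :-1],
                                  asd_idx[None, 1:], wrev[:, 1:]]
        energy = self.init_penalty + np.where(both, stacks, 0.0).sum(axis=1)
        return np.minimum(energy, 0.0)


@dataclass(frozen=True)
class ViennaCofoldEngine:
    """RNA::RNA hybridization via the ViennaRNA (RNAcofold) bindings."""

    name: str = "viennarna-rnacofold"

    def duplex_energy(self, asd: str, window: str) -> float:
        import RNA  # deferred: optional engine

        if len(asd) != len(window):
            raise ValueError("length mismatch")
        encode_rna(asd), encode_rna(window)
        _, mfe = RNA.cofold(f"{asd}&{window}")
        return float(min(0.0, mfe))


def duplex_energy(engine, asd: str, window: str) -> float:
    """dG_binding (kcal/mol, <= 0) of an aSD::window duplex under ``engine``."""
    return engine.duplex_energy(asd, window)


def get_duplex_engine(name: str = "builtin"):
    if name == "builtin":
        return BuiltinDuplexEngine()
    if name == "viennarna":
        return ViennaCofoldEngine()
    raise ValueError(f"unknown duplex engine {name!r}")


def window_at_distance(utr: str, d: int, x: int) -> str:
    """Window of length ``x`` at distance ``d`` (negative int) in a UTR.

    The UTR string is positions -L ... -1 in 5'->3' order; the window covers
    positions -(|d|+x) ... -(|d|+1).
    """
    if d >= 0:
        raise ValueError(f"distance must be negative, got {d}")
    L = len(utr)
    gap = -d
    if gap + x > L:
        raise ValueError(
            f"window out of range: |d|={gap} + x={x} exceeds UTR length {L}"
        )
    return utr[L - gap - x : L - gap]


def core_register_distance(d: int, n_5prime_ext: int) -> int:
    """Distance renumbered to the core-aSD register.

    Extending the aSD 5' by k bases extends the window k bases toward the
    start codon, so a fixed genomic site appears k closer in 3'-end
    numbering; the core-register distance subtracts that shift.
    """
    return d - n_5prime_ext


@dataclass
class BindingProfile:
    """Per-gene map distance -> dG_binding for one aSD candidate."""

    gene_id: str
    asd_sequence: str
    energies: dict[int, float]
    complete: bool = True


def binding_profile(utr: str, asd: str, d_max: int = 14,
                    engine: BuiltinDuplexEngine | None = None,
                    gene_id: str = "") -> BindingProfile:
    """Hybridization energies at distances -1 ... -d_max (d_max events).

    Distances whose window would run past the 5' end of the UTR are omitted
    and the profile is marked incomplete.
    """
    engine = engine or BuiltinDuplexEngine()
    x = len(asd)
    asd_idx = encode_rna(asd)
    energies: dict[int, float] = {}
    complete = True
    L = len(utr)
    for d in range(-1, -d_max - 1, -1):
        if -d + x > L:
            complete = False
            break
        w = encode_rna(window_at_distance(utr, d, x))
        energies[d] = float(engine.duplex_energies(asd_idx, w[None, :])[0])
    return BindingProfile(gene_id, asd, energies, complete)


def binding_energy_matrix(utr_matrix: np.ndarray, asd: str, distances: list[int],
                          engine: BuiltinDuplexEngine | None = None) -> np.ndarray:
    """(n_genes, n_distances) dG_binding for equal-length encoded UTRs.

    ``utr_matrix`` is (n, L) encoded; UTR position -1 is the last column.
    """
    engine = engine or BuiltinDuplexEngine()
    asd_idx = encode_rna(asd)
    x = asd_idx.shape[0]
    L = utr_matrix.shape[1]
    out = np.empty((utr_matrix.shape[0], len(distances)))
    for k, d in enumerate(distances):
        gap = -d
        if gap + x > L:
            raise ValueError(f"window out of range at d={d} for UTR length {L}")
        windows = utr_matrix[:, L - gap - x : L - gap]
        out[:, k] = engine.duplex_energies(asd_idx, windows)
    return out
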