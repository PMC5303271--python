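"""Independent brute-force oracle for gapless duplex hybridization energies.

Enumerates every subset of pairable positions (2^x pairing choices) and
scores each with the packaged stacking table read independently of the
engine's array lookup; the reported energy is the minimum, clipped at zero.
Used to validate the vectorized engine over exhaustive window sets.
"""

import itertools
from importlib import resources

PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def _load_stack_strings():
    stack = {}
    init = None
    text = resources.files("sdscan").joinpath("data/stack_dg37.tsv").read_text()
    for line in text.splitlines():
        if line.startswith("# duplex_initiation"):
            init = float(line.split("\t")[1].split()[0])
            continue
        if not line or line.startswith(("#", "pair1")):
            continue
        p1, p2, dg = line.split("\t")
        stack[(p1, p2)] = float(dg)
    return stack, init


_STACK, _INIT = _load_stack_strings()


def brute_force_duplex(asd: str, window: str) -> float:
    x = len(asd)
    wrev = window[::-1]
    pairable = [i for i in range(x) if (asd[i], wrev[i]) in PAIRS]
    best = 0.0
    for r in range(len(pairable) + 1):
        for chosen in itertools.combinations(pairable, r):
            chosen_set = set(chosen)
            e = _INIT
            for i in range(x - 1):
                if i in chosen_set and i + 1 in chosen_set:
                    e += _STACK[(asd[i] + wrev[i], asd[i + 1] + wrev[i + 1])]
            best = min(best, e)
    return 0.0 if best >= 0 else best
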