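"""Independent brute-force oracles for the descriptor and accuracy math.

Everything here is written as plain position-by-position loops, deliberately
independent of the package's implementations, so tests can compare the two
routes on random inputs.
"""

from collections import Counter

DSSP_STATES = "GHIEBTSL"
STATE_GROUP = {"G": 1, "H": 1, "I": 1, "E": 2, "B": 2, "T": 3, "S": 3, "L": 4}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def segments(symbols):
    """All maximal constant segments as (symbol, start, length)."""
    segs = []
    i = 0
    while i < len(symbols):
        j = i
        while j < len(symbols) and symbols[j] == symbols[i]:
            j += 1
        segs.append((symbols[i], i, j - i))
        i = j
    return segs


def state_composition(s):
    return [sum(1 for c in s if c == st) / len(s) for st in DSSP_STATES]


def group_composition(s):
    groups = [STATE_GROUP[c] for c in s]
    return [sum(1 for g in groups if g == k) / len(s) for k in (1, 2, 3, 4)]


def run_counts(s, alphabet=DSSP_STATES, mapper=None):
    symbols = [mapper[c] for c in s] if mapper else list(s)
    counts = dict.fromkeys(alphabet, 0)
    for sym, _, length in segments(symbols):
        if length >= 2:
            counts[sym] += 1
    return [counts[a] for a in alphabet]


def run_coverage(s, alphabet=DSSP_STATES, mapper=None):
    symbols = [mapper[c] for c in s] if mapper else list(s)
    covered = dict.fromkeys(alphabet, 0)
    for sym, _, length in segments(symbols):
        if length >= 2:
            covered[sym] += length
    return [covered[a] / len(s) for a in alphabet]


def group_alternation(s):
    groups = [STATE_GROUP[c] for c in s]
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    if len(groups) < 2:
        return [0.0] * 4
    for i in range(len(groups) - 1):
        a, b = groups[i], groups[i + 1]
        if a != b:
            counts[a] += 1
            counts[b] += 1
    return [counts[k] / (len(groups) - 1) for k in (1, 2, 3, 4)]


def standard_only(seq):
    return [c for c in seq.upper() if c in AMINO_ACIDS]


def aa_composition(seq):
    std = standard_only(seq)
    return [sum(1 for c in std if c == a) / len(std) for a in AMINO_ACIDS]


def ctd_composition(seq, groups3):
    std = standard_only(seq)
    lut = {aa: g + 1 for g, members in enumerate(groups3) for aa in members}
    return [sum(1 for c in std if lut[c] == k) / len(std) for k in (1, 2, 3)]


def ctd_transition(seq, groups3):
    std = standard_only(seq)
    if len(std) == 1:
        return [0.0, 0.0, 0.0]
    lut = {aa: g + 1 for g, members in enumerate(groups3) for aa in members}
    pairs = Counter()
    for i in range(len(std) - 1):
        a, b = lut[std[i]], lut[std[i + 1]]
        if a != b:
            pairs[frozenset((a, b))] += 1
    order = [frozenset((1, 2)), frozenset((1, 3)), frozenset((2, 3))]
    return [pairs[p] / (len(std) - 1) for p in order]


def ctd_distribution(seq, groups3):
    import math

    std = standard_only(seq)
    lut = {aa: g + 1 for g, members in enumerate(groups3) for aa in members}
    L = len(std)
    out = []
    for k in (1, 2, 3):
        positions = [i + 1 for i, c in enumerate(std) if lut[c] == k]
        if not positions:
            out.extend([0.0] * 5)
            continue
        out.append(positions[0] / L)
        for q in (0.25, 0.5, 0.75, 1.0):
            out.append(positions[max(1, math.ceil(q * len(positions))) - 1] / L)
    return out


def fund_vector(hits, domain_ids, threshold):
    vec = [0.0] * len(domain_ids)
    for i, d in enumerate(domain_ids):
        for hit_id, ev in hits:
            if hit_id == d and ev <= threshold:
                vec[i] = 1.0
    return vec


def q_counts(y_true, y_pred, class_labels):
    """(n_i, c_i, N, C, Q) by explicit counting."""
    n = {c: 0 for c in class_labels}
    correct = {c: 0 for c in class_labels}
    for t, p in zip(y_true, y_pred):
        n[t] += 1
        if t == p:
            correct[t] += 1
    N = sum(n.values())
    C = sum(correct.values())
    return n, correct, N, C, C / N
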