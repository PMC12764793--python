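"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive — explicit window enumeration,
per-character CIGAR expansion, brute-force graph search — and shares no
code with the package internals it checks.
"""

from __future__ import annotations

from collections import Counter

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_count_canonical(sequences, k: int) -> dict[str, int]:
    """Enumerate every window, canonicalise by string comparison, count."""
    if isinstance(sequences, str):
        sequences = [sequences]
    counts: Counter[str] = Counter()
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if any(b not in "ACGT" for b in w):
                continue
            r = rc(w)
            counts[min(w, r)] += 1
    return dict(counts)


def brute_subtract(a: dict[str, int], b: dict[str, int]) -> dict[str, int]:
    return {k: v for k, v in a.items() if k not in b}


def brute_classify(seq: str, set1: dict[str, int], set2: dict[str, int], k: int) -> str:
    """Re-derive the three-way label by direct window membership counting."""
    hits1 = hits2 = 0
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(b not in "ACGT" for b in w):
            continue
        c = min(w, rc(w))
        if c in set1:
            hits1 += 1
        if c in set2:
            hits2 += 1
    s1 = hits1 / len(set1) if set1 else 0.0
    s2 = hits2 / len(set2) if set2 else 0.0
    if s1 > s2:
        return "hap1"
    if s2 > s1:
        return "hap2"
    return "unassigned"


def expand_cigar_breakdown(cigar: str, sv_cutoff: int = 50) -> dict[str, int]:
    """Per-character CIGAR expansion; tallies category base lengths and events."""
    import re

    out = {"match": 0, "snv_count": 0, "snv_len": 0, "indel_count": 0,
           "indel_len": 0, "pav_count": 0, "pav_len": 0, "pav_internal": 0,
           "sc": 0, "total": 0}
    for n_str, op in re.findall(r"(\d+)([=XIDSH])", cigar):
        n = int(n_str)
        expanded = op * n  # one character per base: the naive route
        if op == "=":
            out["match"] += len(expanded)
        elif op == "X":
            out["snv_count"] += len(expanded)
            out["snv_len"] += len(expanded)
        elif op in "ID":
            if n < sv_cutoff:
                out["indel_count"] += 1
                out["indel_len"] += len(expanded)
            else:
                out["pav_count"] += 1
                out["pav_len"] += len(expanded)
                out["pav_internal"] += len(expanded)
        elif op == "S":
            out["sc"] += len(expanded)
            if n >= sv_cutoff:
                out["pav_count"] += 1
                out["pav_len"] += len(expanded)
    out["total"] = (out["match"] + out["snv_len"] + out["indel_len"]
                    + out["pav_internal"] + out["sc"])
    return out


def brute_components(nodes, edges) -> list[set]:
    """Connected components by repeated flood fill."""
    nodes = set(nodes)
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set = set()
    components = []
    for n in sorted(nodes):
        if n in seen:
            continue
        stack, comp = [n], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        components.append(comp)
    return components


def random_sequence(rng, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))
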