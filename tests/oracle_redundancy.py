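"""Independent brute-force oracle for duplicate / transcription detection.

Deliberately written from scratch (its own significant-figure rounding,
its own BFS clustering) so it shares no code with the package
implementation it cross-checks.
"""

from decimal import ROUND_HALF_UP, Decimal
from math import inf, isclose


def sig_round(v: float, n: int) -> float:
    d = Decimal(repr(float(v)))
    if d == 0:
        return 0.0
    shift = (n - 1) - d.adjusted()
    return float(d.scaleb(shift).quantize(Decimal("1"), rounding=ROUND_HALF_UP).scaleb(-shift))


def _eq(a: float, b: float) -> bool:
    return isclose(a, b, rel_tol=1e-6, abs_tol=0.0)


def dup_match(a: float, b: float) -> bool:
    if _eq(a, b):
        return True
    return any(_eq(sig_round(a, n), b) or _eq(a, sig_round(b, n)) for n in (1, 2, 3))


def trans_match(a: float, b: float, decades=(3, 6)) -> bool:
    if a <= 0 or b <= 0:
        return False
    lo, hi = min(a, b), max(a, b)
    return any(dup_match(lo * 10.0**k, hi) for k in decades)


def _components(n: int, edges: list[tuple[int, int]]) -> list[list[int]]:
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen: set[int] = set()
    comps = []
    for start in range(n):
        if start in seen or not adj[start]:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        comps.append(comp)
    return comps


def _flag(members, comps) -> set[str]:
    # members: list of (record_id, document_id, document_year, value)
    flagged = set()
    for comp in comps:
        def key(i):
            rid, doc, year, _ = members[i]
            return (year if year is not None else inf, doc)

        earliest = min(key(i) for i in comp)
        for i in comp:
            if key(i) != earliest:
                flagged.add(members[i][0])
    return flagged


def oracle_duplicates(members) -> set[str]:
    edges = [
        (i, j)
        for i in range(len(members))
        for j in range(i + 1, len(members))
        if members[i][1] != members[j][1] and dup_match(members[i][3], members[j][3])
    ]
    return _flag(members, _components(len(members), edges))


def oracle_transcriptions(members, decades=(3, 6)) -> set[str]:
    edges = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if members[i][1] == members[j][1]:
                continue
            if dup_match(members[i][3], members[j][3]):
                continue
            if trans_match(members[i][3], members[j][3], decades):
                edges.append((i, j))
    flagged = set()
    for comp in _components(len(members), edges):
        def key(i):
            rid, doc, year, _ = members[i]
            return (year if year is not None else inf, doc)

        earliest = min(key(i) for i in comp)
        originals = [members[i][3] for i in comp if key(i) == earliest]
        for i in comp:
            if key(i) == earliest:
                continue
            if any(dup_match(members[i][3], v) for v in originals):
                continue  # faithful citation of the original value
            flagged.add(members[i][0])
    return flagged
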