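"""Independent reference implementations used only by the tests.

Each oracle re-derives its answer by brute force or by an independently
written matcher, never by calling the code under test.
"""

from __future__ import annotations

import itertools
import re


# ---------------------------------------------------------------------------
# PROSITE matching oracle: own parser + backtracking matcher


def _parse_pattern(pattern: str):
    text = pattern.strip().rstrip(".")
    anchor_start = text.startswith("<")
    anchor_end = text.endswith(">")
    text = text.lstrip("<").rstrip(">").strip("-")
    elems = []
    for token in text.split("-"):
        m = re.match(
            r"^(x|[A-Z]|\[[A-Z]+\]|\{[A-Z]+\}|\([A-Z/]+\))"
            r"(?:\((\d+)(?:,(\d+))?\))?$",
            token,
        )
        assert m, f"oracle cannot parse {token!r}"
        body, lo, hi = m.group(1), m.group(2), m.group(3)
        lo = int(lo) if lo else 1
        hi = int(hi) if hi else lo
        if body == "x":
            elems.append(("any", None, lo, hi))
        elif body.startswith("["):
            elems.append(("one_of", set(body[1:-1]), lo, hi))
        elif body.startswith("{"):
            elems.append(("none_of", set(body[1:-1]), lo, hi))
        elif body.startswith("("):
            elems.append(("alts", body[1:-1].split("/"), lo, hi))
        else:
            elems.append(("literal", body, lo, hi))
    return elems, anchor_start, anchor_end


def _elem_matches(seq, i, kind, data):
    """Return list of end positions after consuming one unit at i."""
    if kind == "alts":
        return [i + len(a) for a in data if seq.startswith(a, i)]
    if i >= len(seq):
        return []
    ch = seq[i]
    ok = (
        kind == "any"
        or (kind == "one_of" and ch in data)
        or (kind == "none_of" and ch not in data)
        or (kind == "literal" and ch == data)
    )
    return [i + 1] if ok else []


def _match_from(seq, i, elems, k, anchor_end):
    if k == len(elems):
        if anchor_end and i != len(seq):
            return None
        return i
    kind, data, lo, hi = elems[k]

    def consume(pos, count):
        if count == 0:
            return [pos]
        out = []
        for nxt in _elem_matches(seq, pos, kind, data):
            out.extend(consume(nxt, count - 1))
        return out

    # greedy: longest repetition count first, mirroring regex backtracking
    for count in range(hi, lo - 1, -1):
        for pos in consume(i, count):
            end = _match_from(seq, pos, elems, k + 1, anchor_end)
            if end is not None:
                return end
    return None


def prosite_find_all(pattern: str, seq: str) -> list[tuple[int, int]]:
    """All non-overlapping leftmost matches, (start, end) 0-based half-open."""
    elems, anchor_start, anchor_end = _parse_pattern(pattern)
    hits = []
    i = 0
    while i <= len(seq):
        end = _match_from(seq, i, elems, 0, anchor_end)
        if end is not None and end > i:
            hits.append((i, end))
            i = end
        else:
            i += 1
        if anchor_start:
            break
    return hits


# ---------------------------------------------------------------------------
# chaining oracle: enumerate partitions of the transcription-ordered run


def joinable_oracle(prev, nxt, strand, max_overlap, max_gap):
    """Independent restatement of the exon-joining rules."""
    if nxt.q_start <= prev.q_start:
        return False
    if prev.q_end - nxt.q_start + 1 > max_overlap:
        return False
    lo_p, hi_p = sorted((prev.s_start, prev.s_end))
    lo_n, hi_n = sorted((nxt.s_start, nxt.s_end))
    if strand == "+":
        gap = lo_n - hi_p - 1
    else:
        gap = lo_p - hi_n - 1
    return 0 <= gap < max_gap


def greedy_partitions(ordered, strand, max_overlap, max_gap):
    """The unique partition into consecutive runs obtained by extending
    each run as far as the joining rules allow (greedy from the 5' end),
    found by exhaustive enumeration of all cut sets."""
    n = len(ordered)
    best = None
    for cuts in itertools.product([False, True], repeat=max(n - 1, 0)):
        runs, cur = [], [ordered[0]]
        for hsp, cut in zip(ordered[1:], cuts):
            if cut:
                runs.append(cur)
                cur = [hsp]
            else:
                cur.append(hsp)
        runs.append(cur)
        if any(
            not joinable_oracle(a, b, strand, max_overlap, max_gap)
            for run in runs
            for a, b in zip(run, run[1:])
        ):
            continue
        # greedy from 5': prefer the lexicographically largest run-length
        # profile (longest first run, then longest second, ...)
        profile = tuple(len(r) for r in runs)
        if best is None or profile > best[0]:
            best = (profile, runs)
    assert best is not None  # singleton runs always qualify
    return best[1]


# ---------------------------------------------------------------------------
# monospecific clade oracle: scan every clade of the tree


def monospecific_clades_oracle(root, leaf_group):
    """All maximal monospecific clades as a set of frozen leaf-name sets,
    found by checking every (node, parent) pair independently."""

    def leaves(node):
        if not node.children:
            return [node.name]
        return [x for c in node.children for x in leaves(c)]

    def groups(node):
        return {leaf_group[name] for name in leaves(node)}

    out = set()
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        if len(groups(node)) == 1 and (parent is None or len(groups(parent)) > 1):
            out.add(frozenset(leaves(node)))
        for c in node.children:
            stack.append((c, node))
    return out
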