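"""Brute-force reference detector for tests.

Re-derives the detector's result on small inputs with none of its
machinery: seeds are found by a literal character scan, every edit
bundle of every length is enumerated with ``itertools.product``, all
improving extension chains are followed breadth-first without pruning
or seed skipping, and candidates are assembled by replaying column
lists.  Shares only the scheme definition and the (plumbing) overlap
resolution with the production path.  Refuses sequences beyond
``max_seq_len`` — it is exponential in spirit and meant for fixtures.
"""

from __future__ import annotations

import itertools

from .detect import RepeatHit, dedupe_candidates, resolve_overlaps, _Candidate
from .scoring import ScoringScheme
from .seq_io import SequenceRecord

_OPS = "XID"  # mismatch, insertion, deletion


def _find_seeds_bruteforce(s: str, p: int):
    runs = []
    i = 0
    n = len(s)
    while i + p < n:
        if s[i] == s[i + p] and s[i] != "N":
            j = i
            while j + p < n and s[j] == s[j + p] and s[j] != "N":
                j += 1
            if j - i >= min(p, 4):
                runs.append((i, j))
            i = j
        i += 1
    return runs


def _run(s, u, pos, q, step, scheme):
    """Maximal match/N run from (pos, q); ends on a match column."""
    p = len(u)
    cols = []
    nrun = 0
    while 0 <= pos < len(s):
        c = s[pos]
        if c == "N":
            if nrun == scheme.max_successive_ns:
                break
            nrun += 1
            cols.append((pos, "N", q))
        elif c == u[q]:
            nrun = 0
            cols.append((pos, "M", q))
        else:
            break
        pos += step
        q = (q + step) % p
    while cols and cols[-1][1] == "N":
        cols.pop()
    return cols


def _apply_bundle(s, u, pos, q, step, ops):
    """Replay an explicit op string; None when it is not applicable."""
    p = len(u)
    cols = []
    delta = 0
    for op in ops:
        if op == "D":
            cols.append((None, "D", q))
            q = (q + step) % p
            delta += 0  # scored below
        else:
            if not 0 <= pos < len(s) or s[pos] == "N":
                return None
            if op == "X":
                if s[pos] == u[q]:
                    return None  # a matching column is not an edit
                cols.append((pos, "X", q))
                pos += step
                q = (q + step) % p
            else:
                cols.append((pos, "I", q))
                pos += step
    return pos, q, cols


def _side_closure(s, u, pos0, q0, step, scheme):
    """All endpoints reachable through strictly improving segments."""
    p = len(u)
    ms, xs, gs, ns_ = (
        scheme.match_score,
        scheme.mismatch_score,
        scheme.gap_score,
        scheme.n_score,
    )
    red = scheme.max_score_reduction
    frontier = [(0, pos0, q0, ())]
    seen = {(pos0, q0): 0}
    best = (0, pos0, q0, ())
    while frontier:
        nxt = []
        for gain, pos, q, cols in frontier:
            bundles = [()]
            for blen in range(1, scheme.recursion_depth + 1):
                bundles.extend(itertools.product(_OPS, repeat=blen))
            for ops in bundles:
                applied = _apply_bundle(s, u, pos, q, step, ops)
                if applied is None:
                    continue
                bpos, bq, bcols = applied
                bdelta = sum(xs if op == "X" else gs for _, op, _ in bcols)
                # X-drop: an accepted chain peaks at each segment
                # boundary, so the in-bundle dip is the drop below the
                # side's best score
                if red is not None and bdelta < -red:
                    continue
                rcols = _run(s, u, bpos, bq, step, scheme)
                matches = sum(1 for _, op, _ in rcols if op == "M")
                if matches == 0:
                    continue
                ncols = sum(1 for _, op, _ in rcols if op == "N")
                delta = bdelta + matches * ms + ncols * ns_
                if delta <= 0:
                    continue
                epos = rcols[-1][0] + step
                eq = (rcols[-1][2] + step) % p
                ngain = gain + delta
                if seen.get((epos, eq), -(10**9)) >= ngain:
                    continue
                seen[(epos, eq)] = ngain
                allcols = cols + tuple(bcols) + tuple(rcols)
                nxt.append((ngain, epos, eq, allcols))
                bg, bp_, bq_, _ = best
                if (ngain, step * epos, -eq) > (bg, step * bp_, -bq_):
                    best = (ngain, epos, eq, allcols)
        frontier = nxt
    return best


def _assemble(s, seq_id, r0, r1, p, scheme):
    u = s[r0 : r0 + p]
    ms = scheme.match_score
    seed_len = r1 + p - r0
    rgain, rpos, rq, rcols = _side_closure(s, u, r1 + p, (r1 + p - r0) % p, +1, scheme)
    lgain, lpos, lq, lcols = _side_closure(s, u, r0 - 1, p - 1, -1, scheme)
    start = lpos + 1 if lcols else r0
    end = rpos if rcols else r1 + p
    score = seed_len * ms + lgain + rgain - p * ms

    counts = {"M": seed_len, "X": 0, "I": 0, "D": 0, "N": 0}
    votes: dict[int, dict[str, int]] = {qi: {} for qi in range(p)}
    for i in range(r0, r1 + p):
        qi = (i - r0) % p
        votes[qi][s[i]] = votes[qi].get(s[i], 0) + 1
    matched = set(range(r0, r1 + p))
    for seqpos, op, qi in tuple(lcols) + tuple(rcols):
        counts[op] += 1
        if op in "MX":
            votes[qi][s[seqpos]] = votes[qi].get(s[seqpos], 0) + 1
        if op == "M":
            matched.add(seqpos)
    cons = "".join(
        min(c for c, cnt in votes[qi].items() if cnt == max(votes[qi].values()))
        if votes[qi]
        else u[qi]
        for qi in range(p)
    )
    q_start = lcols[-1][2] if lcols else 0
    unit = cons[q_start:] + cons[:q_start]
    return _Candidate(
        start=start,
        end=end,
        unit_size=p,
        score=score,
        unit=unit,
        n_match=counts["M"],
        n_mismatch=counts["X"],
        n_gap=counts["I"] + counts["D"],
        n_ncol=counts["N"],
        match_positions=frozenset(matched),
    )


def naive_oracle(
    seq: SequenceRecord,
    scheme: ScoringScheme | None = None,
    max_seq_len: int = 500,
) -> list[RepeatHit]:
    """Exhaustive small-scale detection with identical semantics."""
    if scheme is None:
        scheme = ScoringScheme()
    s = seq.residues
    if len(s) > max_seq_len:
        raise ValueError(
            f"naive_oracle refuses sequences longer than {max_seq_len} bp"
        )
    cands = []
    for p in range(scheme.unit_min, scheme.unit_max + 1):
        if len(s) < p + min(p, 4):
            continue
        for r0, r1 in _find_seeds_bruteforce(s, p):
            cand = _assemble(s, seq.id, r0, r1, p, scheme)
            if cand.score >= scheme.min_score(p):
                cands.append(cand)
    hits = [
        RepeatHit(
            sequence_id=seq.id,
            start=c.start,
            end=c.end,
            unit=c.unit,
            unit_size=c.unit_size,
            score=c.score,
            n_match=c.n_match,
            n_mismatch=c.n_mismatch,
            n_gap=c.n_gap,
            n_ncol=c.n_ncol,
        )
        for c in dedupe_candidates(cands)
    ]
    return resolve_overlaps(hits)
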