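"""Seed-and-extend detection of perfect and imperfect tandem repeats.

The detector works per unit size p.  *Seeds* are maximal runs of
in-phase equalities s[i] == s[i+p] (no Ns), kept when the run length
reaches min(p, 4): a perfect tandem of two units, or enough perfect
copies to score 4, whichever is shorter.  Any qualifying repeat whose
longest perfect stretch spans at least one unit plus min(p, 4) bases
contains such a seed.

Each seed is extended independently to the left and to the right in
*segments*: a bundle of 1..recursion_depth consecutive edit columns
(mismatch, insertion or deletion) followed by a maximal run of match/N
columns.  A segment is appended only if it strictly raises the running
score; all improving continuations are explored (branches meet in a
per-(position, phase) best-score memo), and when a maximum score
reduction is configured, bundle branches whose running score falls more
than that amount below the best score seen on the side are abandoned
(an X-drop rule).  N columns score n_score, do not count as edits, and
runs of more than max_successive_ns N columns are never crossed, so
four Ns can bridge two repeat stretches but five cannot.

Candidates from all unit sizes are pooled, deduplicated, annotated with
alternative-unit interpretations, and reduced to a non-overlapping set
(highest score wins; ties to the smaller unit size, then the leftmost
start).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scoring import ScoringScheme
from .seq_io import SequenceRecord
from .units import canonical_motif, canonical_type, is_primitive

_N = "N"
_NEG = -(10**9)

# Alignment column opcodes: M match, X mismatch, N unknown-base column,
# I insertion (sequence char not in the unit tiling), D deletion.
_COL_M, _COL_X, _COL_N, _COL_I, _COL_D = "M", "X", "N", "I", "D"


@dataclass
class RepeatHit:
    """One detected tandem repeat on the analyzed strand.

    ``start``/``end`` are a 0-based half-open interval; ``unit`` is the
    consensus unit rotated into the phase at ``start``; ``alternatives``
    lists competing (unit_size, score) interpretations of the same
    interval, best first (the primary interpretation included).
    """

    sequence_id: str
    start: int
    end: int
    unit: str
    unit_size: int
    score: int
    n_match: int
    n_mismatch: int
    n_gap: int
    n_ncol: int
    alternatives: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def copy_number(self) -> float:
        return self.length / self.unit_size

    @property
    def n_columns(self) -> int:
        return self.n_match + self.n_mismatch + self.n_gap + self.n_ncol

    @property
    def perfection(self) -> float:
        """Percent of alignment columns that are matches, first unit included."""
        return 100.0 * self.n_match / self.n_columns

    @property
    def repeat_type(self) -> str:
        return canonical_type(self.unit)

    @property
    def repeat_motif(self) -> str:
        return canonical_motif(self.unit)


@dataclass
class _Candidate:
    start: int
    end: int
    unit_size: int
    score: int
    unit: str
    n_match: int
    n_mismatch: int
    n_gap: int
    n_ncol: int
    match_positions: frozenset[int]


def _scan_run(s, n, u, p, pos, q, step, ncap, match_score, n_score):
    """Consume a maximal run of match/N columns from (pos, q).

    Returns (n_matches, n_ncols, cols, next_pos, next_q) trimmed so the
    run ends on a match column; cols are (seqpos, op, q) in walk order.
    A run of more than ncap successive N columns is never entered.
    """
    cols = []
    nrun = 0
    i, qq = pos, q
    last_match = -1  # index into cols of the last match column
    while 0 <= i < n:
        c = s[i]
        if c == _N:
            if nrun == ncap:
                break
            nrun += 1
            cols.append((i, _COL_N, qq))
        elif c == u[qq]:
            nrun = 0
            cols.append((i, _COL_M, qq))
            last_match = len(cols) - 1
        else:
            break
        i += step
        qq = (qq + step) % p
    if last_match < 0:
        return 0, 0, [], pos, q
    cols = cols[: last_match + 1]
    n_ncols = sum(1 for _, op, _ in cols if op == _COL_N)
    n_matches = len(cols) - n_ncols
    end_pos = cols[-1][0] + step
    end_q = (cols[-1][2] + step) % p
    return n_matches, n_ncols, cols, end_pos, end_q


def _segments_from(s, n, u, p, pos, q, step, scheme):
    """Enumerate candidate extension segments from state (pos, q).

    Yields (delta, next_pos, next_q, cols).  A segment is a bundle of
    0..recursion_depth edit columns followed by a run with at least one
    match; the zero-edit case only fires when the run opens with N or
    match columns.  X-drop: bundle states dipping more than
    max_score_reduction below the segment start are pruned.
    """
    depth = scheme.recursion_depth
    ncap = scheme.max_successive_ns
    ms, xs, gs, ns_ = (
        scheme.match_score,
        scheme.mismatch_score,
        scheme.gap_score,
        scheme.n_score,
    )
    red = scheme.max_score_reduction
    out = []
    # (pos, q, edits_used, delta, cols)
    stack = [(pos, q, 0, 0, ())]
    pareto: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def _push(npos, nq, nk, ndelta, ncols):
        # X-drop: the running score along an accepted chain peaks at the
        # segment boundary, so a dip of more than the cap within a
        # bundle is exactly a drop of more than the cap below the best
        # score seen on this side.
        if red is not None and ndelta < -red:
            return
        key = (npos, nq)
        entries = pareto.setdefault(key, [])
        for d0, k0 in entries:
            if d0 >= ndelta and k0 <= nk:
                return  # dominated: no better score, no more headroom
        entries.append((ndelta, nk))
        stack.append((npos, nq, nk, ndelta, ncols))

    while stack:
        cpos, cq, k, delta, cols = stack.pop()
        nm, nn, rcols, rpos, rq = _scan_run(
            s, n, u, p, cpos, cq, step, ncap, ms, ns_
        )
        if nm > 0:
            out.append((delta + nm * ms + nn * ns_, rpos, rq, cols + tuple(rcols)))
        if k >= depth:
            continue
        if not 0 <= cpos < n:
            # past the sequence edge: only deletions remain, which can
            # never be followed by a match — dead branch
            continue
        c = s[cpos]
        # deletion: advance the unit, consume nothing
        _push(cpos, (cq + step) % p, k + 1, delta + gs, cols + ((None, _COL_D, cq),))
        if c != _N:
            # insertion: consume c outside the tiling
            _push(cpos + step, cq, k + 1, delta + gs, cols + ((cpos, _COL_I, cq),))
            if c != u[cq]:
                _push(
                    cpos + step,
                    (cq + step) % p,
                    k + 1,
                    delta + xs,
                    cols + ((cpos, _COL_X, cq),),
                )
    return out


def _extend_side(s, n, u, p, pos0, q0, step, scheme):
    """Closure of strictly improving segments in one direction.

    Returns (gain, end_pos, end_q, cols): the best accepted chain of
    segments, where ``end_pos`` is one step past the last consumed
    column.  Ties on gain prefer the farther endpoint, then the smaller
    phase index (deterministic).
    """
    best = (0, pos0, q0, ())
    agenda = [(0, pos0, q0, ())]
    seen = {(pos0, q0): 0}
    while agenda:
        gain, pos, q, cols = agenda.pop()
        for delta, npos, nq, segcols in _segments_from(s, n, u, p, pos, q, step, scheme):
            if delta <= 0:
                continue
            ngain = gain + delta
            key = (npos, nq)
            if seen.get(key, _NEG) >= ngain:
                continue
            seen[key] = ngain
            ncols = cols + segcols
            agenda.append((ngain, npos, nq, ncols))
            b_gain, b_pos, b_q, _ = best
            if (ngain, step * npos, -nq) > (b_gain, step * b_pos, -b_q):
                best = (ngain, npos, nq, ncols)
    return best


def _consensus_unit(u, p, votes, q_start):
    cons = []
    for qi in range(p):
        v = votes[qi]
        if v:
            best_count = max(v.values())
            # count ties broken alphabetically
            cons.append(min(c for c, cnt in v.items() if cnt == best_count))
        else:
            cons.append(u[qi])
    cons = "".join(cons)
    return cons[q_start:] + cons[:q_start]


def _candidate_from_seed(s, n, r0, r1, p, scheme, min_score=None):
    """Extend the perfect seed region [r0, r1+p) both ways; assemble.

    Returns None without assembling the alignment when the best score
    stays below ``min_score``.
    """
    u = s[r0 : r0 + p]
    ms = scheme.match_score
    seed_len = r1 + p - r0
    seed_abs = seed_len * ms

    rgain, rpos, rq, rcols = _extend_side(s, n, u, p, r1 + p, (r1 + p - r0) % p, +1, scheme)
    lgain, lpos, lq, lcols = _extend_side(s, n, u, p, r0 - 1, (p - 1) % p, -1, scheme)

    start = lpos + 1 if lcols else r0
    end = rpos if rcols else r1 + p
    raw = seed_abs + lgain + rgain
    score = raw - p * ms
    if min_score is not None and score < min_score:
        return None

    n_match = seed_len
    n_mismatch = n_gap = n_ncol = 0
    votes: list[dict[str, int]] = [dict() for _ in range(p)]
    for i in range(r0, r1 + p):
        qi = (i - r0) % p
        votes[qi][s[i]] = votes[qi].get(s[i], 0) + 1
    match_positions = set(range(r0, r1 + p))
    q_start = 0
    for cols in (lcols, rcols):
        for seqpos, op, qi in cols:
            if op == _COL_M:
                n_match += 1
                match_positions.add(seqpos)
                votes[qi][s[seqpos]] = votes[qi].get(s[seqpos], 0) + 1
            elif op == _COL_X:
                n_mismatch += 1
                votes[qi][s[seqpos]] = votes[qi].get(s[seqpos], 0) + 1
            elif op == _COL_N:
                n_ncol += 1
            else:
                n_gap += 1
    if lcols:
        q_start = lcols[-1][2]  # last column in walk order = leftmost; a match
    unit = _consensus_unit(u, p, votes, q_start)
    return _Candidate(
        start=start,
        end=end,
        unit_size=p,
        score=score,
        unit=unit,
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_gap=n_gap,
        n_ncol=n_ncol,
        match_positions=frozenset(match_positions),
    )


def find_seeds(s: str, p: int):
    """Maximal runs i..j-1 with s[i] == s[i+p] != N, of length >= min(p, 4)."""
    n = len(s)
    if n < p + 1:
        return []
    codes = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    eq = (codes[:-p] == codes[p:]) & (codes[:-p] != ord("N"))
    if not eq.any():
        return []
    padded = np.concatenate(([False], eq, [False]))
    diffs = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = diffs[::2], diffs[1::2]
    min_run = min(p, 4)
    return [(a, b) for a, b in zip(starts.tolist(), ends.tolist()) if b - a >= min_run]


def anchored_interval_score(s, start, end, unit, scheme, max_cells=2_000_000):
    """Best alignment score of s[start:end] against a perfect tiling of
    ``unit`` anchored at ``start``, covering the interval exactly.

    Used to score alternative unit-size interpretations of a hit.  The
    column rules (recursion depth, N cap, first-unit subtraction) are the
    same as in detection.  Returns None when the interval is too large
    to rescore or no alignment satisfies the constraints.
    """
    p = len(unit)
    L = end - start
    if L * p > max_cells:
        return None
    depth = scheme.recursion_depth
    ncap = scheme.max_successive_ns
    ms, xs, gs, ns_ = (
        scheme.match_score,
        scheme.mismatch_score,
        scheme.gap_score,
        scheme.n_score,
    )
    # state: (q, consecutive_edits, n_run) -> best score
    states = {(0, 0, 0): 0}
    for i in range(start, end):
        c = s[i]
        # deletion closure within this position
        frontier = dict(states)
        for _ in range(depth):
            nxt = {}
            for (q, e, r), sc in frontier.items():
                if e < depth:
                    key = ((q + 1) % p, e + 1, r)
                    val = sc + gs
                    if states.get(key, _NEG) < val:
                        states[key] = val
                        nxt[key] = val
            if not nxt:
                break
            frontier = nxt
        new: dict[tuple[int, int, int], int] = {}

        def _upd(key, val):
            if new.get(key, _NEG) < val:
                new[key] = val

        for (q, e, r), sc in states.items():
            if c == _N:
                if r < ncap:
                    _upd(((q + 1) % p, e, r + 1), sc + ns_)
            else:
                if c == unit[q]:
                    _upd(((q + 1) % p, 0, 0), sc + ms)
                else:
                    if e < depth:
                        _upd(((q + 1) % p, e + 1, 0), sc + xs)
                if e < depth:
                    _upd((q, e + 1, 0), sc + gs)
        states = new
        if not states:
            return None
    return max(states.values()) - p * ms


def alternative_unit_analysis(hit, seq, scheme: ScoringScheme):
    """Competing unit-size interpretations of a hit's interval.

    Candidate unit sizes are the proper divisors of the primary unit
    size and its multiples up to half the hit length, each anchored at
    the hit start; anchored units must be primitive (a periodic anchored
    unit re-describes the same interpretation).  An alternative is
    reported when it qualifies on its own or scores within five edits'
    worth of the primary.  The primary interpretation heads the list.
    """
    s = seq.residues if isinstance(seq, SequenceRecord) else seq
    a, b, p = hit.start, hit.end, hit.unit_size
    L = b - a
    window = 5 * abs(scheme.mismatch_score)
    sizes = [d for d in range(1, p) if p % d == 0]
    m = 2 * p
    while m <= L // 2:
        sizes.append(m)
        m += p
    found = []
    for d in sizes:
        unit_d = s[a : a + d]
        if _N in unit_d or not is_primitive(unit_d):
            continue
        sc = anchored_interval_score(s, a, b, unit_d, scheme)
        if sc is None:
            continue
        if sc >= scheme.min_score(d) or sc >= hit.score - window:
            found.append((d, sc))
    out = [(p, hit.score)] + found
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def dedupe_candidates(cands):
    """Collapse candidates sharing (start, end): keep the best score,
    then the smaller unit size, then the alphabetically first unit."""
    best: dict[tuple[int, int], object] = {}
    for c in cands:
        key = (c.start, c.end)
        prev = best.get(key)
        if prev is None or (-c.score, c.unit_size, c.unit) < (
            -prev.score,
            prev.unit_size,
            prev.unit,
        ):
            best[key] = c
    return sorted(best.values(), key=lambda c: (c.start, c.end, c.unit_size))


def resolve_overlaps(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Greedy non-overlapping selection: higher score wins, ties to the
    smaller unit size, then the leftmost start.  A loser covering exactly
    the winner's interval survives as an alternative interpretation."""
    by_seq: dict[str, list[RepeatHit]] = {}
    for h in hits:
        by_seq.setdefault(h.sequence_id, []).append(h)
    out: list[RepeatHit] = []
    for seq_id in by_seq:
        pool = sorted(
            by_seq[seq_id], key=lambda h: (-h.score, h.unit_size, h.start, h.end)
        )
        accepted: list[RepeatHit] = []
        for h in pool:
            clash = None
            for w in accepted:
                if h.start < w.end and w.start < h.end:
                    clash = w
                    break
            if clash is None:
                accepted.append(h)
            elif (
                clash.start == h.start
                and clash.end == h.end
                and is_primitive(h.unit)
            ):
                clash.alternatives.append((h.unit_size, h.score))
        for h in accepted:
            merged: dict[int, int] = {}
            for usize, sc in [(h.unit_size, h.score)] + h.alternatives:
                if usize not in merged or sc > merged[usize]:
                    merged[usize] = sc
            h.alternatives = sorted(
                ((u_, s_) for u_, s_ in merged.items()), key=lambda t: (-t[1], t[0])
            )
        out.extend(accepted)
    out.sort(key=lambda h: (h.sequence_id, h.start, h.end))
    return out


def _candidates_for_sequence(s: str, scheme: ScoringScheme):
    n = len(s)
    cands: list[_Candidate] = []
    for p in range(scheme.unit_min, scheme.unit_max + 1):
        if n < p + min(p, 4):
            break
        for r0, r1 in find_seeds(s, p):
            cand = _candidate_from_seed(s, n, r0, r1, p, scheme, scheme.min_score(p))
            if cand is not None:
                cands.append(cand)
    return dedupe_candidates(cands)


def find_repeats(seq: SequenceRecord, scheme: ScoringScheme | None = None) -> list[RepeatHit]:
    """All maximal qualifying tandem repeats of a sequence, non-overlapping,
    sorted by start, each annotated with alternative interpretations."""
    if scheme is None:
        scheme = ScoringScheme()
    s = seq.residues
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
        for c in _candidates_for_sequence(s, scheme)
    ]
    hits = resolve_overlaps(hits)
    for h in hits:
        alts = alternative_unit_analysis(h, s, scheme)
        merged: dict[int, int] = {}
        for usize, sc in alts + h.alternatives:
            if usize not in merged or sc > merged[usize]:
                merged[usize] = sc
        h.alternatives = sorted(merged.items(), key=lambda t: (-t[1], t[0]))
    return hits


def find_repeats_all(
    seqs: list[SequenceRecord], scheme: ScoringScheme | None = None
) -> list[RepeatHit]:
    out: list[RepeatHit] = []
    for rec in seqs:
        out.extend(find_repeats(rec, scheme))
    return out


def extend_candidate(seq: SequenceRecord, seed_start: int, seed_end: int, unit: str,
                     scheme: ScoringScheme | None = None) -> RepeatHit | None:
    """Extend one perfect seed occurrence (unit tiling over
    [seed_start, seed_end)) and return the qualifying hit, or None."""
    if scheme is None:
        scheme = ScoringScheme()
    s = seq.residues
    p = len(unit)
    if s[seed_start : seed_start + p] != unit:
        raise ValueError("seed must start with a literal occurrence of the unit")
    span = seed_end - seed_start
    for i in range(seed_start, seed_end):
        if s[i] != unit[(i - seed_start) % p]:
            raise ValueError("seed region is not a perfect tiling of the unit")
    if span < p + 1:
        raise ValueError("seed must cover more than one unit")
    c = _candidate_from_seed(s, len(s), seed_start, seed_end - p, p, scheme)
    if c.score < scheme.min_score(p):
        return None
    return RepeatHit(
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


def score_alignment(columns, unit_size: int, scheme: ScoringScheme | None = None) -> int:
    """Score an explicit column list (ops from 'MXIDN') for a given unit
    size: column scores summed, minus one unscored perfect unit."""
    if scheme is None:
        scheme = ScoringScheme()
    per = {
        _COL_M: scheme.match_score,
        _COL_X: scheme.mismatch_score,
        _COL_I: scheme.gap_score,
        _COL_D: scheme.gap_score,
        _COL_N: scheme.n_score,
    }
    try:
        total = sum(per[op] for op in columns)
    except KeyError as exc:
        raise ValueError(f"unknown alignment column opcode: {exc}") from exc
    return total - unit_size * scheme.match_score
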