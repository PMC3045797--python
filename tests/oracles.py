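"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (plain tuple
arithmetic, exhaustive scans) without reusing the package's helpers.
"""
from __future__ import annotations


def _introns(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return [(a[1], b[0]) for a, b in zip(exons, exons[1:])]


def oracle_classify(chain_a, chain_b, window) -> set[tuple[str, int, int, int]]:
    """Exhaustive enumeration of intron/exon boundary relations.

    Returns {(event_type, start, end, size)}.  Semantics: shared introns are
    silent; introns sharing exactly one transcription-oriented boundary are
    alternative-site events; an intron inside a single exon of the partner
    is a retention; complete exons strictly inside a partner intron whose
    ends coincide with flanking junctions are a skipping event, and the two
    boundary-sharing intron pairs it explains are not double-counted as
    alternative-site events.
    """
    ws, we = window.start, window.end
    strand = chain_a.strand
    ex_a = [(e.start, e.end) for e in chain_a.exons]
    ex_b = [(e.start, e.end) for e in chain_b.exons]
    in_a = [iv for iv in _introns(ex_a) if ws <= iv[0] and iv[1] <= we]
    in_b = [iv for iv in _introns(ex_b) if ws <= iv[0] and iv[1] <= we]

    found: set[tuple[str, int, int, int]] = set()
    suppressed: set[tuple[tuple[int, int], tuple[int, int]]] = set()

    for host_list, other_ex, host_first in ((in_a, ex_b, True), (in_b, ex_a, False)):
        for (s, e) in host_list:
            inside = [(xs, xe) for (xs, xe) in other_ex if s < xs and xe < e]
            if not inside:
                continue
            if not any(xe == s for (_, xe) in other_ex):
                continue
            if not any(xs == e for (xs, _) in other_ex):
                continue
            size = sum(xe - xs for (xs, xe) in inside)
            found.add(("exon_skipping", inside[0][0], inside[-1][1], size))
            for partner in ((s, inside[0][0]), (inside[-1][1], e)):
                suppressed.add(
                    ((s, e), partner) if host_first else (partner, (s, e))
                )

    for host_list, other_ex in ((in_a, ex_b), (in_b, ex_a)):
        for (s, e) in host_list:
            if any(xs <= s and e <= xe for (xs, xe) in other_ex):
                found.add(("intron_retention", s, e, e - s))

    for ia in in_a:
        for ib in in_b:
            if ia == ib or (ia, ib) in suppressed:
                continue
            if strand == "+":
                (da, aa), (db, ab) = ia, ib
            else:
                (aa, da), (ab, db) = ia, ib
            if aa == ab and da != db:
                found.add(("alt_5ss", min(da, db), max(da, db), abs(da - db)))
            elif da == db and aa != ab:
                found.add(("alt_3ss", min(aa, ab), max(aa, ab), abs(aa - ab)))
    return found


def oracle_trim_window(
    quals: list[int], window: int = 20, min_good: int = 15, min_q: int = 20
) -> tuple[int, int] | None:
    """All-windows scan: the base interval kept by quality trimming."""
    n = len(quals)
    if n < window:
        return None
    good = [
        sum(1 for q in quals[i : i + window] if q >= min_q) >= min_good
        for i in range(n - window + 1)
    ]
    best_len = best_start = 0
    i = 0
    while i < len(good):
        if good[i]:
            j = i
            while j < len(good) and good[j]:
                j += 1
            if j - i > best_len:
                best_len, best_start = j - i, i
            i = j
        else:
            i += 1
    if best_len == 0:
        return None
    return best_start, best_start + best_len - 1 + window
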