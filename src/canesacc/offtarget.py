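"""RNAi hairpin off-target screening by exact sequence identity.

An RNAi hairpin is diced into ~21-nt siRNAs, any of which can silence a
transcript it matches perfectly, so off-target risk is governed by the
longest stretch of exact identity between the hairpin target window and
each candidate transcript, and by how many siRNA-length k-mers they share.
Both strands are searched by default because hairpins produce siRNAs from
both arms.

The longest-common-substring search builds a suffix automaton over the
query (linear time/space) and streams each subject through it; its
correctness is defined by — and tested against — the quadratic
dynamic-programming recurrence.  Matching is case-insensitive, U equals T,
and N or any other ambiguity code never matches (conservative for
off-target calls).  Coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "HairpinSpec",
    "OfftargetHit",
    "cds_window",
    "longest_shared_stretch",
    "count_shared_kmers",
    "screen_hairpin",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ACGT = frozenset("ACGT")


def _clean(seq: str, sentinel: str) -> str:
    """Uppercase, U->T; anything not ACGT becomes a non-matching sentinel."""
    s = seq.upper().replace("U", "T")
    return "".join(c if c in _ACGT else sentinel for c in s)


def reverse_complement(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    s = "".join(c if c in _ACGT else "N" for c in s)
    return s.translate(_COMPLEMENT)[::-1]


def cds_window(sequence: str, start: int, end: int) -> str:
    """Subsequence at 1-based inclusive coordinates (length = end - start + 1)."""
    if not (1 <= start <= end <= len(sequence)):
        raise ValueError(
            f"window ({start}, {end}) out of bounds for sequence of length {len(sequence)}"
        )
    return sequence[start - 1 : end]


@dataclass(frozen=True)
class HairpinSpec:
    """Hairpin target window cut from a source CDS (1-based inclusive)."""

    source_id: str
    cds_sequence: str
    start: int
    end: int

    @property
    def target_sequence(self) -> str:
        return cds_window(self.cds_sequence, self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class OfftargetHit:
    subject_id: str
    length: int
    query_start: int = 0  # 1-based inclusive; 0 when length == 0
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0
    strand: str = "+"
    kmer_count: int = 0
    snps_in_stretch: list = field(default_factory=list)


class _SuffixAutomaton:
    """Suffix automaton of the query, used for streaming LCS queries."""

    __slots__ = ("trans", "link", "length", "firstpos", "last")

    def __init__(self, text: str):
        self.trans: list[dict[str, int]] = [{}]
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        self.firstpos: list[int] = [-1]
        self.last = 0
        for i, ch in enumerate(text):
            self._extend(ch, i)

    def _extend(self, ch: str, pos: int) -> None:
        cur = len(self.trans)
        self.trans.append({})
        self.length.append(self.length[self.last] + 1)
        self.link.append(-1)
        self.firstpos.append(pos)
        p = self.last
        while p != -1 and ch not in self.trans[p]:
            self.trans[p][ch] = cur
            p = self.link[p]
        if p == -1:
            self.link[cur] = 0
        else:
            q = self.trans[p][ch]
            if self.length[p] + 1 == self.length[q]:
                self.link[cur] = q
            else:
                clone = len(self.trans)
                self.trans.append(dict(self.trans[q]))
                self.length.append(self.length[p] + 1)
                self.link.append(self.link[q])
                self.firstpos.append(self.firstpos[q])
                while p != -1 and self.trans[p].get(ch) == q:
                    self.trans[p][ch] = clone
                    p = self.link[p]
                self.link[q] = clone
                self.link[cur] = clone
        self.last = cur

    def longest_match(self, subject: str) -> tuple[int, int, int]:
        """(best length, query end index, subject end index), 0-based inclusive ends."""
        best_len = 0
        best_qend = best_send = -1
        v, length = 0, 0
        for i, ch in enumerate(subject):
            while v != 0 and ch not in self.trans[v]:
                v = self.link[v]
                length = self.length[v]
            if ch in self.trans[v]:
                v = self.trans[v][ch]
                length += 1
            else:
                length = 0
            if length > best_len:
                best_len = length
                best_send = i
                best_qend = self.firstpos[v]
        return best_len, best_qend, best_send


def _oriented_match(sam: _SuffixAutomaton, subject_clean: str):
    return sam.longest_match(subject_clean)


def longest_shared_stretch(
    query: str,
    subject: str,
    both_strands: bool = True,
    subject_id: str = "subject",
    variants: list[tuple[int, str, str]] | None = None,
) -> OfftargetHit:
    """Longest exact common substring between query and subject.

    With ``both_strands`` the subject's reverse complement is searched too;
    a plus-strand match wins ties.  ``variants`` is an optional list of
    (subject position 1-based, ref base, alt base); entries falling inside
    the reported stretch are attached as SNP annotations.
    """
    q_clean = _clean(query, "!")
    sam = _SuffixAutomaton(q_clean)
    s_fwd = _clean(subject, "?")
    best_len, qend, send = _oriented_match(sam, s_fwd)
    strand = "+"
    if both_strands:
        s_rev = _clean(reverse_complement(subject), "?")
        rlen, rqend, rsend = _oriented_match(sam, s_rev)
        if rlen > best_len:
            best_len, qend, send, strand = rlen, rqend, rsend, "-"

    hit = OfftargetHit(subject_id=subject_id, length=best_len)
    if best_len == 0:
        return hit
    hit.query_start = qend - best_len + 2  # to 1-based
    hit.query_end = qend + 1
    hit.strand = strand
    if strand == "+":
        hit.subject_start = send - best_len + 2
        hit.subject_end = send + 1
    else:
        n = len(subject)
        # positions on the reverse-complement strand mapped back to the
        # original subject coordinates
        rc_start, rc_end = send - best_len + 2, send + 1
        hit.subject_start = n - rc_end + 1
        hit.subject_end = n - rc_start + 1
    if variants:
        hit.snps_in_stretch = [
            v for v in variants if hit.subject_start <= v[0] <= hit.subject_end
        ]
    return hit


def count_shared_kmers(
    query: str, subject: str, k: int = 21, both_strands: bool = True
) -> int:
    """Distinct query k-mers present in the subject (both strands by default).

    Only unambiguous (pure ACGT) k-mers participate; k defaults to the
    canonical 21-nt siRNA length.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    q = query.upper().replace("U", "T")
    if k > len(q):
        import warnings

        warnings.warn(f"k={k} exceeds query length {len(q)}; no k-mers to match",
                      stacklevel=2)
        return 0

    def kmers(s: str) -> set[str]:
        return {
            s[i : i + k]
            for i in range(len(s) - k + 1)
            if _ACGT.issuperset(s[i : i + k])
        }

    s = subject.upper().replace("U", "T")
    subject_set = kmers(s)
    if both_strands:
        subject_set |= kmers(reverse_complement(s))
    return len(kmers(q) & subject_set)


def screen_hairpin(
    hairpin: HairpinSpec,
    subjects: list[tuple[str, str]] | dict[str, str],
    k: int = 21,
    both_strands: bool = True,
) -> list[OfftargetHit]:
    """Screen the hairpin target against each subject transcript.

    Returns one hit per subject, sorted by identity-stretch length then
    shared k-mer count, both descending.
    """
    if isinstance(subjects, dict):
        items = list(subjects.items())
    else:
        items = list(subjects)
    ids = [sid for sid, _ in items]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dups}")
    query = hairpin.target_sequence
    hits = []
    for sid, seq in items:
        hit = longest_shared_stretch(query, seq, both_strands, subject_id=sid)
        hit.kmer_count = count_shared_kmers(query, seq, k, both_strands)
        hits.append(hit)
    hits.sort(key=lambda h: (-h.length, -h.kmer_count, h.subject_id))
    return hits
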