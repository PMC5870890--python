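"""Repeat-anchored identification of crRNA reads and the 3'-end profile.

A mature crRNA carries a spacer followed by a 5' portion of the CRISPR
direct repeat; the position of its 3' end within the repeat marks the Cas6
processing site.  A collapsed read qualifies as CRISPR-derived when:

1. it contains the first five bases of the repeat (the seed) — the leftmost
   occurrence anchors the decomposition into upstream bases and the
   "processed repeat" (the read suffix from the seed onward);
2. the processed repeat is at least 12 nt long (the repeat-length route),
   OR it is shorter but the 5 bases immediately upstream match a known
   native spacer ending (the junction route: 5 spacer bases + >= 5 repeat
   bases = at least 10 bases across the spacer-repeat junction);
3. the processed repeat is a left-anchored, mismatch-free prefix of the
   repeat (fidelity) — reads that read through into the next spacer fail
   this and are reported separately, as they indicate unprocessed
   pre-crRNA signal.

Qualified reads are histogrammed by processed-repeat length (equivalently,
by 3'-end position within the repeat) and normalized to the count of reads
containing a 25-nt substring of a highly expressed reference gene, making
profiles comparable across samples.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from crrnaseq.formats_io import PathLike, PipelineParams, SpacerEndSet

SEED_LENGTH = 5
MIN_REPEAT_ROUTE_LENGTH = 12
JUNCTION_UPSTREAM_LENGTH = 5
REFERENCE_KMER_LENGTH = 25

Route = Literal["repeat_length", "junction", "rejected"]
RejectReason = Literal[
    "no_seed", "too_short_no_junction", "fidelity_fail", "upstream_too_short"
]


@dataclass(frozen=True)
class RepeatMatch:
    """A read's repeat-anchored decomposition and its qualification outcome."""

    identifier: str
    seed_offset: int
    upstream: str
    processed_repeat: str
    route: Route
    reject_reason: Optional[RejectReason] = None

    @property
    def qualified(self) -> bool:
        return self.route != "rejected"

    @property
    def length(self) -> int:
        """Processed-repeat length = 3'-end position within the repeat (1-based)."""
        return len(self.processed_repeat)


@dataclass(frozen=True)
class ReferenceIndex:
    """All distinct 25-nt substrings of the reference gene (sense strand)."""

    kmers: frozenset[str]
    k: int = REFERENCE_KMER_LENGTH


@dataclass
class CrrnaProfile:
    """Histogram of processed-repeat lengths, normalized to the reference gene.

    ``counts[l]`` is the number of qualified reads whose 3' end sits at
    repeat position ``l`` (1-based, ``l`` in [1, len(repeat)]);
    ``heights[l] = counts[l] / n_reference * y_scale``.
    """

    counts: dict[int, int]
    n_reference: int
    n_qualified: int
    heights: dict[int, float]
    repeat_length: int


# ---------------------------------------------------------------------------
# Filtering primitives
# ---------------------------------------------------------------------------


def find_repeat_start(insert: str, repeat: str) -> Optional[int]:
    """Position of the leftmost exact occurrence of the repeat's first 5 bases.

    Returns None when the seed is absent; N never matches.
    """
    if len(repeat) < SEED_LENGTH:
        raise ValueError(f"repeat must be at least {SEED_LENGTH} nt")
    pos = insert.find(repeat[:SEED_LENGTH])
    return pos if pos >= 0 else None


def check_junction(upstream: str, spacer_ends: SpacerEndSet) -> bool:
    """True iff the last 5 upstream bases match a known native spacer ending."""
    if len(upstream) < JUNCTION_UPSTREAM_LENGTH:
        return False
    return upstream[-JUNCTION_UPSTREAM_LENGTH:] in spacer_ends


def check_fidelity(processed_repeat: str, repeat: str) -> bool:
    """True iff the processed repeat is a left-anchored substring of the repeat.

    It may be shorter than the repeat but must match at the 5' end with no
    mismatches; anything longer than the repeat (read-through) fails.
    """
    return len(processed_repeat) <= len(repeat) and repeat.startswith(processed_repeat)


def qualify_read(
    insert: str,
    repeat: str,
    spacer_ends: SpacerEndSet,
    identifier: str = "",
) -> RepeatMatch:
    """Apply the full qualification pipeline to one read.

    Order: seed search; upstream removal; length/junction gate for short
    processed repeats; fidelity last.  Only the leftmost seed occurrence is
    considered — a fidelity failure rejects the read outright rather than
    re-scanning later occurrences.
    """
    pos = find_repeat_start(insert, repeat)
    if pos is None:
        return RepeatMatch(identifier, 0, "", "", "rejected", "no_seed")
    upstream, processed = insert[:pos], insert[pos:]
    if len(processed) < MIN_REPEAT_ROUTE_LENGTH:
        if len(upstream) < JUNCTION_UPSTREAM_LENGTH:
            return RepeatMatch(
                identifier, pos, upstream, processed, "rejected", "upstream_too_short"
            )
        if not check_junction(upstream, spacer_ends):
            return RepeatMatch(
                identifier, pos, upstream, processed, "rejected", "too_short_no_junction"
            )
        route: Route = "junction"
    else:
        route = "repeat_length"
    if not check_fidelity(processed, repeat):
        return RepeatMatch(identifier, pos, upstream, processed, "rejected", "fidelity_fail")
    return RepeatMatch(identifier, pos, upstream, processed, route)


# ---------------------------------------------------------------------------
# Reference-gene counting
# ---------------------------------------------------------------------------


def build_reference_index(reference: str, k: int = REFERENCE_KMER_LENGTH) -> ReferenceIndex:
    """Index all consecutive length-k windows of the reference (sense strand)."""
    if len(reference) < k:
        raise ValueError(f"reference must be at least {k} nt (got {len(reference)})")
    return ReferenceIndex(
        kmers=frozenset(reference[i : i + k] for i in range(len(reference) - k + 1)),
        k=k,
    )


def is_reference_read(insert: str, index: ReferenceIndex) -> bool:
    """True iff some length-25 window of the read is a reference substring.

    Reads shorter than 25 nt never count; each read contributes at most one
    to the reference tally regardless of how many windows match.  Matching
    is exact and sense-strand only (the library is strand-specific).
    """
    k = index.k
    return any(insert[i : i + k] in index.kmers for i in range(len(insert) - k + 1))


# ---------------------------------------------------------------------------
# Profile construction and rendering
# ---------------------------------------------------------------------------


def build_profile(
    matches: Iterable[RepeatMatch],
    n_reference: int,
    params: PipelineParams,
) -> CrrnaProfile:
    """Histogram qualified matches by processed-repeat length and normalize.

    Raises when ``n_reference`` is zero: the normalization is undefined and
    a different (expressed) reference gene should be supplied.
    """
    if n_reference <= 0:
        raise ValueError(
            "no reads matched the reference gene; normalization is undefined — "
            "choose a reference gene that is expressed in this dataset"
        )
    repeat_len = len(params.repeat)
    counts: dict[int, int] = {}
    n_qualified = 0
    for m in matches:
        if not m.qualified:
            continue
        n_qualified += 1
        counts[m.length] = counts.get(m.length, 0) + 1
    heights = {l: c / n_reference * params.y_scale for l, c in counts.items()}
    return CrrnaProfile(
        counts=counts,
        n_reference=n_reference,
        n_qualified=n_qualified,
        heights=heights,
        repeat_length=repeat_len,
    )


def profile_table(profile: CrrnaProfile, repeat: str):
    """The profile as a DataFrame: position (1-based), base, raw count, height."""
    import pandas as pd

    rows = [
        {
            "position": l,
            "base": repeat[l - 1],
            "raw_count": profile.counts.get(l, 0),
            "normalized_height": profile.heights.get(l, 0.0),
        }
        for l in range(1, len(repeat) + 1)
    ]
    return pd.DataFrame(rows, columns=["position", "base", "raw_count", "normalized_height"])


def render_profile(
    profile: CrrnaProfile,
    repeat: str,
    out_path: PathLike,
    title: str = "",
) -> tuple[str, str]:
    """Write the per-base 3'-end bar chart and its companion TSV.

    One bar per repeat position (1..len(repeat)), X tick labels are the
    repeat bases, bar height is the normalized count (0 where no read ends
    there).  ``out_path`` is the image path; the TSV drops in beside it with
    a ``.tsv`` extension.  Returns (image_path, tsv_path).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = os.fspath(out_path)
    table = profile_table(profile, repeat)
    tsv_path = os.path.splitext(out_path)[0] + ".tsv"
    table.to_csv(tsv_path, sep="\t", index=False)

    fig, ax = plt.subplots(figsize=(max(6.0, 0.28 * len(repeat)), 3.5))
    ax.bar(table["position"], table["normalized_height"], width=0.8, color="#2b6cb0")
    ax.set_xticks(table["position"])
    ax.set_xticklabels(table["base"], fontsize=7, family="monospace")
    ax.set_xlabel("CRISPR repeat sequence (5' to 3')")
    ax.set_ylabel("crRNA 3' ends\n(normalized to reference)")
    if title:
        ax.set_title(title)
    ax.set_xlim(0.25, len(repeat) + 0.75)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path, tsv_path


# ---------------------------------------------------------------------------
# Per-file orchestration
# ---------------------------------------------------------------------------


@dataclass
class ProfileLog:
    """Per-file counters for the filtering stage."""

    n_total: int = 0
    n_seed_found: int = 0
    n_repeat_route: int = 0
    n_junction_route: int = 0
    n_rejected: dict[str, int] = field(default_factory=dict)
    n_reference: int = 0
    n_both_reference_and_crrna: int = 0

    def as_dict(self) -> dict[str, int]:
        d = {
            "n_total": self.n_total,
            "n_seed_found": self.n_seed_found,
            "n_repeat_route": self.n_repeat_route,
            "n_junction_route": self.n_junction_route,
            "n_reference": self.n_reference,
            "n_both_reference_and_crrna": self.n_both_reference_and_crrna,
        }
        for reason, n in sorted(self.n_rejected.items()):
            d[f"n_rejected_{reason}"] = n
        return d


def profile_reads(
    records: Iterable[tuple[str, str]],
    params: PipelineParams,
    spacer_ends: SpacerEndSet,
    weight_by_count: bool = False,
) -> tuple[CrrnaProfile, ProfileLog, list[RepeatMatch]]:
    """Qualify every (header, insert) record and build the normalized profile.

    Counting is per collapsed read: each record contributes 1 to the repeat
    histogram and at most 1 to the reference tally, because collapsing
    already defines the molecule count.  ``weight_by_count`` instead weights
    each record by the pre-collapse duplicate count encoded in its header
    (``_x<count>_``), for diagnostics only.

    A read can in principle match both the reference and the repeat (only if
    the two sequences overlap); such reads count in both tallies and are
    logged.
    """
    from crrnaseq.trim_collapse import parse_collapsed_header

    ref_index = build_reference_index(params.reference)
    log = ProfileLog()
    matches: list[RepeatMatch] = []
    counts: dict[int, int] = {}
    n_qualified = 0
    n_reference = 0
    for header, insert in records:
        weight = 1
        if weight_by_count:
            _, weight, _ = parse_collapsed_header(header)
        log.n_total += weight
        is_ref = is_reference_read(insert, ref_index)
        if is_ref:
            n_reference += weight
        m = qualify_read(insert, params.repeat, spacer_ends, identifier=header)
        matches.append(m)
        if m.route == "rejected":
            if m.reject_reason != "no_seed":
                log.n_seed_found += weight
            log.n_rejected[m.reject_reason] = log.n_rejected.get(m.reject_reason, 0) + weight
        else:
            log.n_seed_found += weight
            if m.route == "repeat_length":
                log.n_repeat_route += weight
            else:
                log.n_junction_route += weight
            counts[m.length] = counts.get(m.length, 0) + weight
            n_qualified += weight
            if is_ref:
                log.n_both_reference_and_crrna += weight
    log.n_reference = n_reference
    if n_reference <= 0:
        raise ValueError(
            "no reads matched the reference gene; normalization is undefined — "
            "choose a reference gene that is expressed in this dataset"
        )
    heights = {l: c / n_reference * params.y_scale for l, c in counts.items()}
    profile = CrrnaProfile(
        counts=counts,
        n_reference=n_reference,
        n_qualified=n_qualified,
        heights=heights,
        repeat_length=len(params.repeat),
    )
    return profile, log, matches


def select_files_by_keyword(directory: PathLike, keyword: str) -> list[str]:
    """FASTA files in a directory whose base name contains the keyword.

    The keyword can be any part of the file name; returns paths in
    lexicographic order of base name.  Raises if the directory is missing.
    """
    directory = os.fspath(directory)
    if not os.path.isdir(directory):
        raise FileNotFoundError(f"no such directory: {directory}")
    names = sorted(
        n
        for n in os.listdir(directory)
        if n.endswith((".fasta", ".fa")) and keyword in n
    )
    return [os.path.join(directory, n) for n in names]
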