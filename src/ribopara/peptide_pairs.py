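"""Discriminating peptide pairs and paralog stoichiometry estimation.

Two paralogous proteins typically differ at only a handful of residues, so
their tryptic digests contain *pairs* of unique peptides of identical
length that differ by one or two amino acids -- for example DIDQHAVTK
(RpS19b) versus EIDQHVVTK (RpS19a), which differ at two positions. Because
such near-identical peptides have comparable physicochemical behaviour,
the ratio of their summed reporter S/N directly estimates the relative
copy number of the two paralogs within the purified ribosome population:
a log2 difference (alternative minus canonical) of 0 means equal
incorporation, +2 means four alternative-containing ribosomes for every
canonical one.

Pair matching replaces the manual curation used in practice with a
deterministic rule: candidate pairs (equal length, Hamming distance within
bounds, both peptides unique to their paralog) are greedily selected in
order of (substitution count, aligned-coordinate offset), each peptide
used at most once. A pair is *anchored* when the canonical peptide's
coordinates map onto the alternative peptide's interval through a global
alignment of the two parent sequences -- evidence that the two peptides
really are homologous stretches rather than coincidental lookalikes;
unanchored pairs are kept in the match list but excluded from ratio
estimation by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median
from typing import Sequence

import pandas as pd
from Bio import Align

from .digestion import DigestParams, PeptideIndex, build_peptide_index, digest_protein
from .quantify import SampleDesign, SN_PREFIX
from .registry import Registry


def hamming(a: str, b: str) -> int:
    """Number of mismatched positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class PeptidePairMatch:
    """A matched near-identical unique-peptide pair of one paralog group."""

    group_id: str
    pep_canonical: str
    pep_alternative: str
    n_subs: int
    sub_positions: tuple[int, ...]  # 1-based within the peptide
    anchored: bool
    start_canonical: int  # 1-based in the canonical parent
    start_alternative: int

    @property
    def label(self) -> str:
        """Bracketed-substitution label, e.g. ``[D]IDQH[A]VTK/[E]IDQH[V]VTK``."""
        return (
            _bracket(self.pep_canonical, self.sub_positions)
            + "/"
            + _bracket(self.pep_alternative, self.sub_positions)
        )


def _bracket(seq: str, positions: tuple[int, ...]) -> str:
    out = []
    pos = set(positions)
    for i, ch in enumerate(seq, start=1):
        out.append(f"[{ch}]" if i in pos else ch)
    return "".join(out)


def _alignment_map(seq_a: str, seq_b: str) -> dict[int, int]:
    """0-based coordinate map a->b from a global pairwise alignment."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    mapping: dict[int, int] = {}
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for off in range(a1 - a0):
            mapping[a0 + off] = b0 + off
    return mapping


def find_discriminating_pairs(
    registry: Registry,
    group_id: str,
    digest_params: DigestParams | None = None,
    min_subs: int = 1,
    max_subs: int = 2,
    index: PeptideIndex | None = None,
) -> list[PeptidePairMatch]:
    """Match near-identical unique tryptic peptides between a pair's members.

    Returns matches sorted by canonical-peptide start. Groups without
    usable unique peptides (identical-sequence pairs, or pairs whose
    differences destroy or create cleavage sites so peptide lengths no
    longer agree) yield an empty list, not an error.
    """
    if min_subs < 1:
        raise ValueError("min_subs must be >= 1")
    if max_subs < min_subs:
        raise ValueError("max_subs must be >= min_subs")
    params = digest_params or DigestParams()
    group = registry.group(group_id)
    if index is None:
        index = build_peptide_index(registry, params)

    def unique_peps(acc: str) -> list:
        uniq = index.unique_peptides(acc)
        peps = [p for p in digest_protein(registry, acc, params) if p.sequence in uniq]
        seen: dict[str, object] = {}
        for p in peps:  # one entry per sequence; first (leftmost) occurrence
            seen.setdefault(p.sequence, p)
        return list(seen.values())

    can_peps = unique_peps(group.canonical)
    alt_peps = unique_peps(group.alternative)
    if not can_peps or not alt_peps:
        return []

    coord_map = _alignment_map(
        registry.protein(group.canonical).sequence,
        registry.protein(group.alternative).sequence,
    )

    candidates = []
    for pc in can_peps:
        for pa in alt_peps:
            if len(pc.sequence) != len(pa.sequence):
                continue
            d = hamming(pc.sequence, pa.sequence)
            if not (min_subs <= d <= max_subs):
                continue
            mapped = coord_map.get(pc.start - 1)
            if mapped is not None:
                offset = abs(mapped - (pa.start - 1))
                anchored = (
                    pa.start - 1 <= mapped < pa.start - 1 + len(pa.sequence)
                )
            else:
                offset, anchored = math.inf, False
            candidates.append((d, offset, pc, pa, anchored))

    candidates.sort(key=lambda c: (c[0], c[1], c[2].sequence, c[3].sequence))
    used_c: set[str] = set()
    used_a: set[str] = set()
    matches = []
    for d, offset, pc, pa, anchored in candidates:
        if pc.sequence in used_c or pa.sequence in used_a:
            continue
        used_c.add(pc.sequence)
        used_a.add(pa.sequence)
        subs = tuple(
            i + 1
            for i, (x, y) in enumerate(zip(pc.sequence, pa.sequence))
            if x != y
        )
        matches.append(
            PeptidePairMatch(
                group_id=group_id,
                pep_canonical=pc.sequence,
                pep_alternative=pa.sequence,
                n_subs=d,
                sub_positions=subs,
                anchored=anchored,
                start_canonical=pc.start,
                start_alternative=pa.start,
            )
        )
    matches.sort(key=lambda m: m.start_canonical)
    return matches


@dataclass
class PairRatioEstimate:
    """Per-replicate paralog log2 fold difference (alternative - canonical).

    ``log2_diff`` is the median over matched pairs and is None when no pair
    had reporter signal on both sides; per-pair values are always retained
    because individual pairs are informative on their own.
    """

    group_id: str
    tissue: str
    complex: str
    replicate: str
    log2_diff: float | None
    n_pairs_used: int
    n_pairs_skipped: int
    per_pair: dict[str, float]


def estimate_pair_ratio(
    matches: Sequence[PeptidePairMatch],
    psms: pd.DataFrame,
    design: SampleDesign,
    tissue: str,
    complex: str = "m80S",
    replicate: str | None = None,
    *,
    method: str = "sum",
    anchored_only: bool = True,
    require_charge_overlap: bool = False,
) -> PairRatioEstimate:
    """Estimate the paralog log2 fold difference for one tissue/replicate.

    For each matched pair, reporter S/N is summed over the tissue's
    channels and over all PSMs of each peptide; the per-pair value is
    log2(alt/can) whenever both sums are positive, and pairs with a zero
    or absent side are skipped and counted. ``method="mean"`` divides each
    side by its PSM count first (average per-PSM S/N instead of total).
    ``require_charge_overlap`` additionally demands that the two peptides'
    observed charge-state sets intersect, a proxy for comparable
    ionization behaviour.
    """
    if method not in ("sum", "mean"):
        raise ValueError(f"unknown method {method!r}")
    cols = design.sample_columns(
        tissue=tissue, complex=complex, replicate=replicate, include_pooled=False
    )
    group_id = matches[0].group_id if matches else ""
    peptide_pool = {m.pep_canonical for m in matches} | {
        m.pep_alternative for m in matches
    }
    runs = {run for run, _ in cols}
    relevant = psms[
        psms["peptide"].isin(peptide_pool) & psms["run"].isin(runs)
    ]

    def side(peptide: str) -> tuple[float, int, set]:
        total, n, charges = 0.0, 0, set()
        sub = relevant[relevant["peptide"] == peptide]
        for run, ch in cols:
            col = SN_PREFIX + ch
            if col not in sub.columns:
                continue
            vals = sub.loc[sub["run"] == run, col].dropna()
            total += float(vals.sum())
            n += int(len(vals))
        charges = set(sub["charge"].tolist())
        return total, n, charges

    per_pair: dict[str, float] = {}
    skipped = 0
    for m in matches:
        if anchored_only and not m.anchored:
            skipped += 1
            continue
        s_can, n_can, q_can = side(m.pep_canonical)
        s_alt, n_alt, q_alt = side(m.pep_alternative)
        if require_charge_overlap and not (q_can & q_alt):
            skipped += 1
            continue
        if s_can <= 0 or s_alt <= 0:
            skipped += 1
            continue
        if method == "mean":
            s_can, s_alt = s_can / n_can, s_alt / n_alt
        per_pair[m.label] = math.log2(s_alt / s_can)

    return PairRatioEstimate(
        group_id=group_id,
        tissue=tissue,
        complex=complex,
        replicate=replicate if replicate is not None else "all",
        log2_diff=median(per_pair.values()) if per_pair else None,
        n_pairs_used=len(per_pair),
        n_pairs_skipped=skipped,
        per_pair=per_pair,
    )


def write_matches(matches: Sequence[PeptidePairMatch], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(
            "group_id\tpep_canonical\tpep_alternative\tn_subs\t"
            "sub_positions\tanchored\tstart_canonical\tstart_alternative\n"
        )
        for m in matches:
            fh.write(
                f"{m.group_id}\t{m.pep_canonical}\t{m.pep_alternative}\t"
                f"{m.n_subs}\t{','.join(map(str, m.sub_positions))}\t"
                f"{m.anchored}\t{m.start_canonical}\t{m.start_alternative}\n"
            )


def write_estimates(estimates: Sequence[PairRatioEstimate], path) -> None:
    """Long-format per-pair table (group, pair label, tissue, replicate, log2)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("group_id\tpair\ttissue\tcomplex\treplicate\tlog2_diff\n")
        for e in estimates:
            for label, value in e.per_pair.items():
                fh.write(
                    f"{e.group_id}\t{label}\t{e.tissue}\t{e.complex}\t"
                    f"{e.replicate}\t{value:.10g}\n"
                )
            fh.write(
                f"{e.group_id}\t<median>\t{e.tissue}\t{e.complex}\t"
                f"{e.replicate}\t"
                + (f"{e.log2_diff:.10g}" if e.log2_diff is not None else "NA")
                + "\n"
            )
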