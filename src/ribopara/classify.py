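"""Per-tissue paralog status calls and RNA/protein concordance.

Two independent lines of evidence feed each call: (i) the enrichment test
-- is the alternative paralog significantly more abundant in this tissue
than in a reference tissue? -- and (ii) the discriminating-peptide-pair
stoichiometry estimate m, the median across replicates of the
alternative-minus-canonical log2 fold difference within the tissue's
ribosomes. The statuses:

* ``switched``            alternative enriched and m >= switch_threshold
                          (the alternative occupies most ribosomes);
* ``co_equal``            |m| <= equal_band (the two paralogs are present
                          at about equal levels; takes precedence because
                          stoichiometry evidence is more direct);
* ``enriched_minor``      alternative enriched but m <= -switch_threshold
                          (up-regulated yet still a minority species);
* ``canonical_dominant``  everything else with data;
* ``insufficient_data``   no ratio estimate and no enrichment call, e.g.
                          a sequence-identical pair or one with no
                          detectable unique peptides.

The numeric boundaries (switch_threshold = 1 log2 unit, i.e. alternative at
least twice the canonical, and equal_band = 0.5) are explicit
operationalisations of the qualitative notions "larger proportion" and
"around equal levels"; both are configuration fields.

RNA/protein concordance asks whether a protein-level fold change between
two tissues is mirrored at the transcript level (RPKM), distinguishing
transcriptionally driven enrichment from incorporation-level regulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

import pandas as pd

from .enrichment import ComparisonResult
from .peptide_pairs import PairRatioEstimate
from .registry import Registry

STATUSES = (
    "switched",
    "co_equal",
    "enriched_minor",
    "canonical_dominant",
    "insufficient_data",
)

CONCORDANCE = ("concordant", "protein_only", "rna_only", "neither")


@dataclass(frozen=True)
class ParalogCall:
    """Status of one paralog pair in one tissue, with its evidence."""

    group_id: str
    tissue: str
    status: str
    alternative_enriched: bool | None  # None when no enrichment call exists
    median_log2_diff: float | None
    n_replicates: int


def _tissue_of_label(label: str) -> str:
    return label.split(":", 1)[0]


def call_status(
    registry: Registry,
    enrichment_results: Sequence[ComparisonResult],
    ratio_estimates: Sequence[PairRatioEstimate],
    switch_threshold: float = 1.0,
    equal_band: float = 0.5,
) -> list[ParalogCall]:
    """Integrate enrichment calls and pair ratios into per-tissue statuses.

    Enrichment evidence is read from comparison labels of the form
    ``tissue:complex``: the alternative counts as enriched in tissue T when
    any comparison with T on either side calls it enriched on that side.
    Relabelling canonical<->alternative in the registry maps switched to
    enriched_minor (and back) and leaves co_equal fixed.
    """
    if switch_threshold <= 0:
        raise ValueError("switch_threshold must be > 0")
    if equal_band < 0:
        raise ValueError("equal_band must be >= 0")

    # (tissue, accession) -> enriched? ; presence of key = "a call exists"
    enrich: dict[tuple[str, str], bool] = {}
    for r in enrichment_results:
        ta = _tissue_of_label(r.group_a)
        tb = _tissue_of_label(r.group_b)
        key_a, key_b = (ta, r.protein), (tb, r.protein)
        enrich[key_a] = enrich.get(key_a, False) or (r.enriched_in == "a")
        enrich[key_b] = enrich.get(key_b, False) or (r.enriched_in == "b")

    by_pair: dict[tuple[str, str], list[float]] = {}
    tissues_seen: set[tuple[str, str]] = set()
    for e in ratio_estimates:
        key = (e.group_id, e.tissue)
        tissues_seen.add(key)
        if e.log2_diff is not None:
            by_pair.setdefault(key, []).append(e.log2_diff)

    all_tissues = {t for t, _ in enrich} | {t for _, t in tissues_seen}
    calls = []
    for gid in sorted(registry.groups):
        group = registry.groups[gid]
        for tissue in sorted(all_tissues):
            values = by_pair.get((gid, tissue), [])
            m = median(values) if values else None
            key = (tissue, group.alternative)
            has_enrich = key in enrich
            alt_enriched = enrich.get(key)
            if m is None and not has_enrich:
                status = "insufficient_data"
            elif m is not None and abs(m) <= equal_band:
                status = "co_equal"
            elif (
                m is not None
                and bool(alt_enriched)
                and m >= switch_threshold
            ):
                status = "switched"
            elif (
                m is not None
                and bool(alt_enriched)
                and m <= -switch_threshold
            ):
                status = "enriched_minor"
            else:
                status = "canonical_dominant"
            calls.append(
                ParalogCall(
                    group_id=gid,
                    tissue=tissue,
                    status=status,
                    alternative_enriched=alt_enriched,
                    median_log2_diff=m,
                    n_replicates=len(values),
                )
            )
    return calls


@dataclass(frozen=True)
class RnaProteinRecord:
    """A gene's RNA-level vs protein-level fold change between two tissues."""

    gene_symbol: str
    rna_log2fc: float
    protein_log2fc: float
    concordance: str


def rna_protein_concordance(
    rna_table: pd.DataFrame,
    protein_results: Sequence[ComparisonResult],
    tissue_a: str,
    tissue_b: str,
    threshold_log2: float = math.log2(1.5),
    pseudocount: float = 0.1,
    gene_symbols: Mapping[str, str] | None = None,
) -> list[RnaProteinRecord]:
    """Classify genes by agreement of RNA and protein fold changes.

    ``rna_table`` is a gene_symbol x tissue RPKM grid; a pseudocount admits
    zero-RPKM genes. ``concordant`` requires both |fold changes| above the
    threshold with the same sign; ``protein_only``/``rna_only`` when only
    one level moves; ``neither`` otherwise (including the rare
    opposite-sign case). Protein results are joined by gene symbol via
    ``gene_symbols`` (accession -> symbol), defaulting to identity.
    """
    if {tissue_a, tissue_b} - set(rna_table.columns):
        raise ValueError(f"RNA table lacks tissues {tissue_a!r}/{tissue_b!r}")
    records = []
    matched = 0
    for r in protein_results:
        if not math.isfinite(r.log2fc):
            continue
        symbol = (gene_symbols or {}).get(r.protein, r.protein)
        if symbol not in rna_table.index:
            continue
        matched += 1
        rpkm_a = float(rna_table.at[symbol, tissue_a])
        rpkm_b = float(rna_table.at[symbol, tissue_b])
        rna_fc = math.log2((rpkm_a + pseudocount) / (rpkm_b + pseudocount))
        rna_up = abs(rna_fc) > threshold_log2
        prot_up = abs(r.log2fc) > threshold_log2
        if rna_up and prot_up and (rna_fc > 0) == (r.log2fc > 0):
            cls = "concordant"
        elif prot_up and not rna_up:
            cls = "protein_only"
        elif rna_up and not prot_up:
            cls = "rna_only"
        else:
            cls = "neither"
        records.append(
            RnaProteinRecord(
                gene_symbol=symbol,
                rna_log2fc=rna_fc,
                protein_log2fc=r.log2fc,
                concordance=cls,
            )
        )
    if not matched:
        raise ValueError("no overlapping genes between RNA and protein tables")
    return records


def summary_report(calls: Sequence[ParalogCall], registry: Registry) -> dict:
    """Per-tissue headline lists (alternative gene symbols by status)."""
    tissues: dict[str, dict[str, list[str]]] = {}
    for call in calls:
        alt_symbol = registry.gene_symbol(registry.groups[call.group_id].alternative)
        bucket = tissues.setdefault(
            call.tissue, {s: [] for s in STATUSES}
        )
        bucket[call.status].append(alt_symbol)
    for bucket in tissues.values():
        for s in STATUSES:
            bucket[s] = sorted(bucket[s])
    return {"tissues": tissues}


def write_calls(calls: Sequence[ParalogCall], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(
            "group_id\ttissue\tstatus\talternative_enriched\t"
            "median_log2_diff\tn_replicates\n"
        )
        for c in calls:
            m = "NA" if c.median_log2_diff is None else f"{c.median_log2_diff:.10g}"
            e = "NA" if c.alternative_enriched is None else str(c.alternative_enriched)
            fh.write(
                f"{c.group_id}\t{c.tissue}\t{c.status}\t{e}\t{m}\t{c.n_replicates}\n"
            )
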