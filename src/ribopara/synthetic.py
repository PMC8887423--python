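"""Synthetic TMT experiment generator with ground truth.

The generator emulates the statistical structure a paralog-resolved TMT
analysis assumes, so every downstream stage can be tested without any
deposited data:

* per (tissue, paralog group) an *alternative fraction* f sets the paralog
  stoichiometry: canonical copy number L*R*(1-f), alternative L*R*f, where
  R is the tissue's ribosome abundance and L a per-channel loading factor;
  non-paralog proteins get L*R*multiplier;
* each peptide has a multiplicative ionization efficiency e_p, log-normal
  with median 1 (so zero spread degenerates to exactly 1 and closed-form
  checks become exact);
* spectral counts per (peptide, run) are Poisson with mean psm_depth*e_p
  -- one spectrum carries all reporter channels of its run, matching TMT
  multiplexing;
* each PSM's reporter S/N in a channel is copy_number * e_p * eps with eps
  log-normal(median 1, sd sigma_r) drawn independently per channel;
* each run's pooled reference channel carries the mean copy number over
  the run's sample channels;
* an RNA table gives RPKM proportional to copy numbers with independent
  log-normal noise, so RNA/protein concordance classes are non-degenerate.

Homologous discriminating-pair peptides are *coupled* by default: the
alternative peptide inherits its canonical partner's efficiency and
spectral-count draws. This encodes the assumption that makes the
peptide-pair estimator valid in the first place -- near-identical peptides
ionize and sample comparably -- and it is what makes the zero-noise pair
ratio exactly log2(f/(1-f)) in every replicate. Independent draws are a
flag away (``pair_coupling=False``) for studying estimator robustness when
that assumption fails.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import ParalogCall
from .digestion import DigestParams, build_peptide_index, digest_protein
from .peptide_pairs import PairRatioEstimate, find_discriminating_pairs
from .quantify import AbundanceMatrix, SampleDesign, SN_PREFIX
from .registry import ParalogGroup, ProteinRecord, Registry


@dataclass
class SimTruth:
    """Ground-truth stoichiometry and abundance parameters.

    ``alt_fraction`` maps (tissue, group_id) -> f in [0, 1]; unlisted pairs
    fall back to ``default_alt_fraction``. ``ribosome_abundance`` (per
    tissue) and ``loading`` (per run/channel) default to 1; ``multipliers``
    set relative abundances of non-paralog proteins.
    """

    alt_fraction: dict[tuple[str, str], float] = field(default_factory=dict)
    default_alt_fraction: float = 0.05
    ribosome_abundance: dict[str, float] = field(default_factory=dict)
    loading: dict[tuple[str, str], float] = field(default_factory=dict)
    multipliers: dict[str, float] = field(default_factory=dict)
    rna_base: float = 50.0

    def fraction(self, tissue: str, group_id: str) -> float:
        f = self.alt_fraction.get((tissue, group_id), self.default_alt_fraction)
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"alt_fraction {f} outside [0, 1]")
        return f

    @classmethod
    def from_yaml(cls, source) -> "SimTruth":
        if hasattr(source, "read"):
            raw = yaml.safe_load(source)
        else:
            raw = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
        fractions = {
            (tissue, gid): float(f)
            for tissue, groups in (raw.get("alt_fraction") or {}).items()
            for gid, f in groups.items()
        }
        return cls(
            alt_fraction=fractions,
            default_alt_fraction=float(raw.get("default_alt_fraction", 0.05)),
            ribosome_abundance={
                k: float(v) for k, v in (raw.get("ribosome_abundance") or {}).items()
            },
            multipliers={
                k: float(v) for k, v in (raw.get("multipliers") or {}).items()
            },
            rna_base=float(raw.get("rna_base", 50.0)),
        )


@dataclass
class SimConfig:
    """Experiment-scale and noise settings; the seed is mandatory."""

    seed: int
    tissues: tuple[str, ...] = ("testis", "ovary", "head", "embryo")
    n_replicates: int = 3
    psm_depth: float = 5.0
    sigma_e: float = 0.3
    sigma_r: float = 0.3
    sigma_rna: float = 0.2
    digest: DigestParams = field(default_factory=DigestParams)
    complex: str = "m80S"
    pooled_channel: bool = True
    pair_coupling: bool = True
    min_subs: int = 1
    max_subs: int = 2

    def __post_init__(self) -> None:
        if self.psm_depth <= 0:
            raise ValueError("psm_depth must be > 0")
        for name in ("sigma_e", "sigma_r", "sigma_rna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class SimResult:
    """Simulated tables plus the truth they were generated from."""

    psms: pd.DataFrame
    design: SampleDesign
    rna: pd.DataFrame
    truth: SimTruth
    config: SimConfig
    copy_numbers: pd.DataFrame  # accession x tissue (loading excluded)


def _copy_number(
    registry: Registry, truth: SimTruth, accession: str, tissue: str
) -> float:
    rec = registry.protein(accession)
    r_t = truth.ribosome_abundance.get(tissue, 1.0)
    if rec.group_id is not None:
        f = truth.fraction(tissue, rec.group_id)
        share = f if rec.role == "alternative" else 1.0 - f
        return r_t * share
    return r_t * truth.multipliers.get(accession, 1.0)


def simulate(registry: Registry, config: SimConfig, truth: SimTruth) -> SimResult:
    """Generate PSM, design and RNA tables for one multi-run TMT experiment.

    One run per biological replicate; within a run, one reporter channel
    per tissue plus (optionally) a pooled reference channel.
    """
    rng = np.random.default_rng(config.seed)
    runs = [f"TMT{i + 1}" for i in range(config.n_replicates)]
    replicates = [f"rep{i + 1}" for i in range(config.n_replicates)]
    channels = [f"c{i + 1:02d}" for i in range(len(config.tissues))]
    pooled_ch = f"c{len(config.tissues) + 1:02d}" if config.pooled_channel else None

    design_rows = []
    for run, rep in zip(runs, replicates):
        for ch, tissue in zip(channels, config.tissues):
            design_rows.append((run, ch, tissue, config.complex, rep, False))
        if pooled_ch:
            design_rows.append((run, pooled_ch, "pool", config.complex, rep, True))
    design = SampleDesign(
        pd.DataFrame(design_rows, columns=SampleDesign.COLUMNS)
    )

    # Digest everything once. PSMs are generated per peptide *sequence* --
    # one spectrum per detection event, as a search engine would report --
    # with the S/N carrying the summed copy number of all parent proteins
    # and the proteins column listing them all.
    index = build_peptide_index(registry, config.digest)
    peptides: list[str] = sorted(index.parents)

    # Efficiency / spectral-count coupling keys: by default each peptide
    # sequence is its own key; homologous discriminating-pair peptides
    # share their canonical partner's draws.
    key: dict[str, str] = {p: p for p in peptides}
    if config.pair_coupling:
        for gid in sorted(registry.groups):
            group = registry.groups[gid]
            if group.sequence_identical:
                continue
            for m in find_discriminating_pairs(
                registry,
                gid,
                config.digest,
                min_subs=config.min_subs,
                max_subs=config.max_subs,
                index=index,
            ):
                key[m.pep_alternative] = m.pep_canonical

    base_keys = sorted(set(key.values()))
    if config.sigma_e > 0:
        draws = np.exp(rng.normal(0.0, config.sigma_e, size=len(base_keys)))
    else:
        draws = np.ones(len(base_keys))
    efficiency = dict(zip(base_keys, draws))

    counts: dict[tuple[str, tuple[str, str]], int] = {}
    for run in runs:
        lam = np.array([config.psm_depth * efficiency[k] for k in base_keys])
        ks = rng.poisson(lam)
        for bk, k in zip(base_keys, ks):
            counts[(run, bk)] = int(k)

    copy = pd.DataFrame(
        {
            tissue: [
                _copy_number(registry, truth, acc, tissue)
                for acc in sorted(registry.proteins)
            ]
            for tissue in config.tissues
        },
        index=sorted(registry.proteins),
    )

    sn_cols = [SN_PREFIX + ch for ch in channels]
    if pooled_ch:
        sn_cols.append(SN_PREFIX + pooled_ch)
    rows = []
    for run in runs:
        for pep in peptides:
            e_p = efficiency[key[pep]]
            k = counts[(run, key[pep])]
            if k == 0:
                continue
            parent_list = sorted(index.parents_of(pep))
            base = [
                sum(copy.at[acc, tissue] for acc in parent_list)
                for tissue in config.tissues
            ]
            if pooled_ch:
                base.append(float(np.mean(base)))  # pool mixes the samples
            loads = [
                truth.loading.get((run, ch), 1.0)
                for ch in (channels + [pooled_ch] if pooled_ch else channels)
            ]
            chan_copy = np.asarray(base) * np.asarray(loads)
            parents = ";".join(parent_list)
            for _ in range(k):
                if config.sigma_r > 0:
                    eps = np.exp(rng.normal(0.0, config.sigma_r, size=len(chan_copy)))
                else:
                    eps = 1.0
                sn = chan_copy * e_p * eps
                charge = int(rng.integers(2, 4))
                qvalue = float(rng.uniform(0.0, 0.05))
                rows.append((pep, parents, charge, run, qvalue, *sn))
    psms = pd.DataFrame(
        rows, columns=["peptide", "proteins", "charge", "run", "qvalue", *sn_cols]
    )
    psms["proteins"] = [tuple(p.split(";")) for p in psms["proteins"]]

    rna_rows = {}
    for acc in sorted(registry.proteins):
        symbol = registry.gene_symbol(acc)
        vals = []
        for tissue in config.tissues:
            noise = (
                math.exp(rng.normal(0.0, config.sigma_rna))
                if config.sigma_rna > 0
                else 1.0
            )
            vals.append(truth.rna_base * copy.at[acc, tissue] * noise)
        rna_rows[symbol] = vals
    rna = pd.DataFrame.from_dict(
        rna_rows, orient="index", columns=list(config.tissues)
    )
    rna.index.name = "gene_symbol"

    return SimResult(
        psms=psms, design=design, rna=rna, truth=truth, config=config, copy_numbers=copy
    )


def null_log_normal_matrix(
    n_proteins: int = 2000,
    n_a: int = 3,
    n_b: int = 3,
    sigma: float = 0.3,
    seed: int = 0,
) -> AbundanceMatrix:
    """Null abundance matrix: equal means, i.i.d. multiplicative noise.

    Two pseudo-tissues ("a", "b") with ``n_a``/``n_b`` channels across as
    many runs; every value is exp(N(0, sigma)). This is the configuration
    under which the enrichment t-test's type-I error is calibrated.
    """
    rng = np.random.default_rng(seed)
    design_rows = []
    cols = []
    for i in range(max(n_a, n_b)):
        run, rep = f"TMT{i + 1}", f"rep{i + 1}"
        if i < n_a:
            design_rows.append((run, "c01", "a", "m80S", rep, False))
            cols.append((run, "c01"))
        if i < n_b:
            design_rows.append((run, "c02", "b", "m80S", rep, False))
            cols.append((run, "c02"))
    design = SampleDesign(pd.DataFrame(design_rows, columns=SampleDesign.COLUMNS))
    values = pd.DataFrame(
        np.exp(rng.normal(0.0, sigma, size=(n_proteins, len(cols)))),
        index=[f"P{i:05d}" for i in range(n_proteins)],
        columns=pd.MultiIndex.from_tuples(cols, names=["run", "channel"]),
    )
    return AbundanceMatrix(values=values, stage="normalized", design=design)


def make_toy_registry(
    n_pairs: int = 1,
    n_singletons: int = 4,
    n_blocks: int = 8,
    n_sub_blocks: int = 4,
    block_len: int = 8,
    subs_per_block: int = 1,
    identical: bool = False,
    seed: int = 20,
) -> Registry:
    """Small registry for fast simulation studies.

    Proteins are concatenations of tryptic "blocks" (K/R-terminated,
    interior free of K/R/P); each paralog pair's alternative member carries
    ``subs_per_block`` substitutions in ``n_sub_blocks`` of its blocks, so
    the pair has exactly that many equal-length discriminating peptides at
    zero missed cleavages.
    """
    rng = np.random.default_rng(seed)
    interior = np.array(list("ACDEFGHILMNQSTVWY"))
    used_blocks: set[str] = set()

    def new_block() -> str:
        while True:
            body = "".join(rng.choice(interior, size=block_len - 1))
            tail = "K" if rng.random() < 0.5 else "R"
            if body + tail not in used_blocks:
                used_blocks.add(body + tail)
                return body + tail

    def mutate(block: str, n_subs: int) -> str:
        body = list(block)
        positions = rng.choice(len(block) - 1, size=n_subs, replace=False)
        for pos in positions:
            choices = [c for c in interior if c != body[pos]]
            body[pos] = str(rng.choice(choices))
        out = "".join(body)
        if out in used_blocks:
            return mutate(block, n_subs)
        used_blocks.add(out)
        return out

    proteins, groups = [], []
    for g in range(n_pairs):
        gid = f"G{g + 1}"
        can_blocks = [new_block() for _ in range(n_blocks)]
        if identical:
            alt_blocks = list(can_blocks)
        else:
            alt_blocks = list(can_blocks)
            for b in range(1, 1 + n_sub_blocks):  # skip N-terminal block
                alt_blocks[b] = mutate(can_blocks[b], subs_per_block)
        can_acc, alt_acc = f"CAN{g + 1}", f"ALT{g + 1}"
        proteins.append(
            ProteinRecord(can_acc, can_acc, "".join(can_blocks), "SSU", gid, "canonical")
        )
        proteins.append(
            ProteinRecord(alt_acc, alt_acc, "".join(alt_blocks), "SSU", gid, "alternative")
        )
        groups.append(ParalogGroup(gid, can_acc, alt_acc, identical))
    for s in range(n_singletons):
        acc = f"SGL{s + 1}"
        seq = "".join(new_block() for _ in range(n_blocks))
        proteins.append(ProteinRecord(acc, acc, seq, "LSU"))
    return Registry(proteins, groups)


def truth_status(
    registry: Registry,
    truth: SimTruth,
    group_id: str,
    tissue: str,
    reference_tissue: str,
    switch_threshold: float = 1.0,
    equal_band: float = 0.5,
    enrichment_fold: float = 1.5,
) -> str:
    """Status label implied by the ground truth, using the same decision rule."""
    group = registry.group(group_id)
    if group.sequence_identical:
        return "insufficient_data"
    f = truth.fraction(tissue, group_id)
    alt_here = _copy_number(registry, truth, group.alternative, tissue)
    alt_ref = _copy_number(registry, truth, group.alternative, reference_tissue)
    enriched = alt_ref > 0 and alt_here / alt_ref > enrichment_fold
    if f <= 0 or f >= 1:
        m = math.inf if f >= 1 else -math.inf
    else:
        m = math.log2(f / (1 - f))
    if abs(m) <= equal_band:
        return "co_equal"
    if enriched and m >= switch_threshold:
        return "switched"
    if enriched and m <= -switch_threshold:
        return "enriched_minor"
    return "canonical_dominant"


def recovery_report(
    registry: Registry,
    truth: SimTruth,
    estimates: Sequence[PairRatioEstimate],
    calls: Sequence[ParalogCall] | None = None,
    reference_tissue: str | None = None,
    switch_threshold: float = 1.0,
    equal_band: float = 0.5,
) -> dict:
    """Compare estimates (and optionally status calls) with the truth.

    Per (tissue, group) with a defined truth log-odds, reports the true and
    estimated log2 fold differences and their difference (bias); aggregates
    mean bias and RMSE. With ``calls`` and a reference tissue, also scores
    status-label accuracy against the truth-implied labels.
    """
    by_pair: dict[tuple[str, str], list[float]] = {}
    for e in estimates:
        if e.log2_diff is not None:
            by_pair.setdefault((e.group_id, e.tissue), []).append(e.log2_diff)

    entries = {}
    errors = []
    for (gid, tissue), values in sorted(by_pair.items()):
        f = truth.fraction(tissue, gid)
        if not 0 < f < 1:
            continue
        true_m = math.log2(f / (1 - f))
        est_m = median(values)
        entries[f"{tissue}/{gid}"] = {
            "true_log2_diff": true_m,
            "estimated_log2_diff": est_m,
            "bias": est_m - true_m,
            "n_replicates": len(values),
        }
        errors.append(est_m - true_m)

    report: dict = {
        "pairs": entries,
        "bias": float(np.mean(errors)) if errors else None,
        "rmse": float(np.sqrt(np.mean(np.square(errors)))) if errors else None,
    }
    if calls is not None and reference_tissue is not None:
        scored = 0
        correct = 0
        for c in calls:
            if c.tissue == reference_tissue:
                continue
            expected = truth_status(
                registry,
                truth,
                c.group_id,
                c.tissue,
                reference_tissue,
                switch_threshold,
                equal_band,
            )
            scored += 1
            correct += int(c.status == expected)
        report["label_accuracy"] = correct / scored if scored else None
    return report


def write_sim(result: SimResult, outdir) -> dict[str, Path]:
    """Write the simulated tables in the dialects the pipeline consumes."""
    from .quantify import write_psm_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "psms": outdir / "psms.tsv",
        "design": outdir / "design.tsv",
        "rna": outdir / "rna.tsv",
        "truth": outdir / "truth.yaml",
    }
    write_psm_table(result.psms, paths["psms"])
    result.design.write(paths["design"])
    result.rna.to_csv(paths["rna"], sep="\t")
    truth = result.truth
    fractions: dict[str, dict[str, float]] = {}
    for (tissue, gid), f in sorted(truth.alt_fraction.items()):
        fractions.setdefault(tissue, {})[gid] = f
    paths["truth"].write_text(
        yaml.safe_dump(
            {
                "default_alt_fraction": truth.default_alt_fraction,
                "alt_fraction": fractions,
                "ribosome_abundance": truth.ribosome_abundance,
                "multipliers": truth.multipliers,
                "rna_base": truth.rna_base,
            },
            sort_keys=True,
        ),
        encoding="utf-8",
    )
    return paths


def gonad_switching_truth() -> SimTruth:
    """The bundled integration-test truth.

    Encodes the qualitative gonad findings as stand-in alternative
    fractions: in testis the RpL22 and RpL37 pairs are switched (f = 0.8),
    RpS19 and RpS5 sit at parity (f = 0.5) and RpS15A/RpS10/RpS28 are
    enriched minorities (f = 0.1); in ovary RpS5 is switched (f = 0.8) and
    the RpL24/RpL7/RpLP0 alternatives are enriched minorities (f = 0.25).
    Everywhere else the canonical paralog dominates (f = 0.05).
    """
    import io
    from importlib import resources

    source = resources.files("ribopara.data") / "gonad_switching_truth.yaml"
    return SimTruth.from_yaml(io.StringIO(source.read_text(encoding="utf-8")))
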