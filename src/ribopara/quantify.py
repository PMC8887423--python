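"""PSM-table ingestion and the abundance processing chain.

Reporter-ion quantitation with isobaric tags (TMT) yields, per
peptide-spectrum match (PSM), one signal-to-noise (S/N) value per reporter
channel. Protein *abundance* in a channel is the sum of S/N over all PSMs
matched to the protein. The chain then proceeds:

raw -> normalized   column (channel) totals equalised, so each TMT tag
                    carries the same total signal;
     -> scaled      each value divided by a per-run reference: either the
                    run's pooled-sample channel or the mean of the run's
                    sample channels ("replicate_mean");
     -> zscore      row-standardised values for clustering heatmaps.

Missing reporter values are genuine non-detections: they are excluded from
sums and references, never imputed as zero.

PSM tables are tab-separated with header columns ``peptide``, ``proteins``
(semicolon-separated accessions), ``charge``, ``run``, ``qvalue`` (optional,
empty allowed) and one ``sn_<channel>`` column per reporter channel; an
empty reporter cell means missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .digestion import PeptideIndex, UNIQUE
from .registry import Registry

logger = logging.getLogger(__name__)

STAGES = ("raw", "normalized", "scaled", "zscore")
SN_PREFIX = "sn_"
COMPLEXES = ("m80S", "polysome")


class SampleDesign:
    """Channel -> (tissue, complex, replicate) map for one or more TMT runs.

    Each row describes one reporter channel of one run; ``is_pooled`` marks
    the run's pooled-reference channel (at most one per run).
    """

    COLUMNS = ("run", "channel", "tissue", "complex", "replicate", "is_pooled")

    def __init__(self, table: pd.DataFrame) -> None:
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"design table missing columns {sorted(missing)}")
        table = table.loc[:, list(self.COLUMNS)].copy()
        table["is_pooled"] = table["is_pooled"].map(_to_bool)
        if table.duplicated(["run", "channel"]).any():
            raise ValueError("duplicate (run, channel) rows in design")
        pooled_per_run = table.groupby("run")["is_pooled"].sum()
        if (pooled_per_run > 1).any():
            raise ValueError("more than one pooled channel in a run")
        bad = set(table["complex"]) - set(COMPLEXES)
        if bad:
            raise ValueError(f"unknown complex values {sorted(bad)}")
        self.table = table.reset_index(drop=True)

    @classmethod
    def read(cls, path) -> "SampleDesign":
        sep = "," if str(path).endswith(".csv") else "\t"
        return cls(pd.read_csv(path, sep=sep, dtype=str))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def runs(self) -> list[str]:
        return list(dict.fromkeys(self.table["run"]))

    def columns(self) -> list[tuple[str, str]]:
        """All (run, channel) sample keys, in design order."""
        return list(zip(self.table["run"], self.table["channel"]))

    def pooled_channel(self, run: str) -> str | None:
        sub = self.table[(self.table["run"] == run) & self.table["is_pooled"]]
        return None if sub.empty else str(sub["channel"].iloc[0])

    def sample_columns(
        self,
        tissue: str | None = None,
        complex: str | None = None,
        replicate: str | None = None,
        run: str | None = None,
        include_pooled: bool = False,
    ) -> list[tuple[str, str]]:
        """(run, channel) keys matching the given selectors."""
        t = self.table
        mask = pd.Series(True, index=t.index)
        if not include_pooled:
            mask &= ~t["is_pooled"]
        for col, val in (
            ("tissue", tissue),
            ("complex", complex),
            ("replicate", replicate),
            ("run", run),
        ):
            if val is not None:
                mask &= t[col] == val
        return list(zip(t.loc[mask, "run"], t.loc[mask, "channel"]))


@dataclass
class AbundanceMatrix:
    """Protein x channel abundance grid with an explicit processing stage.

    ``values`` is indexed by accession with a (run, channel) column
    MultiIndex; missing cells are NaN.
    """

    values: pd.DataFrame
    stage: str
    design: SampleDesign | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise ValueError(
                f"operation requires stage in {stages}, matrix is "
                f"{self.stage!r}"
            )

    def write(self, path) -> None:
        flat = self.values.copy()
        flat.columns = [f"{r}:{c}" for r, c in self.values.columns]
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(f"# stage={self.stage}\n")
            flat.to_csv(fh, sep="\t", index_label="accession")

    @classmethod
    def read(cls, path, design: SampleDesign | None = None) -> "AbundanceMatrix":
        with open(path, "rt", encoding="utf-8") as fh:
            header = fh.readline().strip()
            if not header.startswith("# stage="):
                raise ValueError("matrix file lacks '# stage=' header")
            stage = header.split("=", 1)[1]
            flat = pd.read_csv(fh, sep="\t", index_col="accession")
        flat.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split(":", 1)) for c in flat.columns], names=["run", "channel"]
        )
        return cls(values=flat, stage=stage, design=design)


def read_psm_table(path) -> pd.DataFrame:
    """Read the tab-separated PSM dialect into a DataFrame.

    The ``proteins`` column is parsed into tuples of accessions; reporter
    columns stay as ``sn_<channel>`` floats with NaN for missing.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "proteins", "charge", "run"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PSM table missing columns {sorted(missing)}")
    df["proteins"] = [
        tuple(p.split(";")) for p in df["proteins"].astype(str)
    ]
    if "qvalue" not in df.columns:
        df["qvalue"] = np.nan
    sn_cols = reporter_columns(df)
    if not sn_cols:
        raise ValueError("PSM table has no sn_<channel> reporter columns")
    df[sn_cols] = df[sn_cols].astype(float)
    return df


def write_psm_table(psms: pd.DataFrame, path) -> None:
    out = psms.copy()
    out["proteins"] = [";".join(p) for p in out["proteins"]]
    out.to_csv(path, sep="\t", index=False)


def reporter_columns(psms: pd.DataFrame) -> list[str]:
    return [c for c in psms.columns if c.startswith(SN_PREFIX)]


def filter_psms(
    psms: pd.DataFrame,
    max_qvalue: float = 0.05,
    require_unique: bool = False,
    index: PeptideIndex | None = None,
) -> pd.DataFrame:
    """Apply the identification-confidence and uniqueness filters.

    PSMs with ``qvalue`` above ``max_qvalue`` are removed; the boundary is
    inclusive (a 5% FDR filter keeps q = 0.05 exactly). PSMs lacking a
    q-value are retained and counted in the log. With ``require_unique``,
    only PSMs whose stripped peptide classifies as unique in ``index``
    survive -- the filter that makes paralogs distinguishable.
    """
    keep = psms["qvalue"].isna() | (psms["qvalue"] <= max_qvalue)
    n_noq = int(psms["qvalue"].isna().sum())
    if n_noq:
        logger.info("retained %d PSMs without q-values", n_noq)
    out = psms.loc[keep]
    if require_unique:
        if index is None:
            raise ValueError("require_unique needs a peptide index")
        unique_mask = out["peptide"].map(index.classify) == UNIQUE
        out = out.loc[unique_mask]
    return out.reset_index(drop=True)


def aggregate(
    psms: pd.DataFrame, registry: Registry, design: SampleDesign
) -> AbundanceMatrix:
    """Sum reporter S/N per (protein, run, channel) into a raw matrix.

    Every PSM contributes its S/N once per listed protein (multi-protein
    PSMs are expected to be rare after the uniqueness filter and are
    logged). Proteins with no PSMs are absent from the matrix -- never
    represented as zero rows. Unknown accessions raise with the full list
    of offenders.
    """
    unknown = sorted(
        {acc for prots in psms["proteins"] for acc in prots}
        - set(registry.proteins)
    )
    if unknown:
        raise ValueError(f"PSMs assigned to unknown accessions: {unknown}")
    n_multi = int((psms["proteins"].map(len) > 1).sum())
    if n_multi:
        logger.info("%d PSMs list multiple proteins; counted once per protein", n_multi)

    sn_cols = reporter_columns(psms)
    long = psms[["proteins", "run", *sn_cols]].explode("proteins")
    long = long.rename(columns={"proteins": "accession"})
    # min_count=1 keeps all-missing cells as NaN instead of 0
    summed = long.groupby(["accession", "run"])[sn_cols].sum(min_count=1)

    cols = design.columns()
    values = pd.DataFrame(
        np.nan,
        index=sorted({a for a, _ in summed.index}),
        columns=pd.MultiIndex.from_tuples(cols, names=["run", "channel"]),
    )
    for (acc, run), row in summed.iterrows():
        for col in sn_cols:
            ch = col[len(SN_PREFIX):]
            if (run, ch) in values.columns:
                values.loc[acc, (run, ch)] = row[col]
    return AbundanceMatrix(values=values, stage="raw", design=design)


def normalize_total(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Equalise column totals (the "total peptide amount" normalization).

    Each column is multiplied by mean(column totals)/its total, so every
    channel ends up carrying the same total signal; the common target (the
    mean) keeps magnitudes interpretable. Within-column ratios between
    proteins are preserved exactly.
    """
    matrix.require_stage("raw")
    totals = matrix.values.sum(axis=0, skipna=True)
    if (totals <= 0).any() or totals.isna().any():
        bad = [f"{r}:{c}" for (r, c), t in totals.items() if not t > 0]
        raise ValueError(f"columns with non-positive total: {bad}")
    factors = totals.mean() / totals
    return AbundanceMatrix(
        values=matrix.values * factors,
        stage="normalized",
        design=matrix.design,
    )


def scale(
    matrix: AbundanceMatrix, mode: str, design: SampleDesign | None = None
) -> AbundanceMatrix:
    """Scale normalized abundances to a per-run reference.

    ``mode="pooled"`` divides each cell by the same protein's value in the
    run's pooled channel (so the pooled channel itself becomes 1 where
    defined); ``mode="replicate_mean"`` divides by the protein's mean across
    the run's non-pooled channels. Division by a missing or zero reference
    yields a missing cell.
    """
    matrix.require_stage("normalized")
    design = design or matrix.design
    if design is None:
        raise ValueError("scale requires a sample design")
    if mode not in ("pooled", "replicate_mean"):
        raise ValueError(f"unknown scale mode {mode!r}")

    out = matrix.values.copy()
    for run in design.runs:
        run_cols = [c for c in matrix.values.columns if c[0] == run]
        if not run_cols:
            continue
        if mode == "pooled":
            pooled = design.pooled_channel(run)
            if pooled is None:
                raise ValueError(f"run {run} has no pooled channel")
            ref = matrix.values[(run, pooled)]
        else:
            sample_cols = [
                c for c in run_cols
                if c in set(design.sample_columns(run=run, include_pooled=False))
            ]
            ref = matrix.values[sample_cols].mean(axis=1, skipna=True)
        ref = ref.where(ref > 0)  # zero or missing reference -> missing cells
        for col in run_cols:
            out[col] = matrix.values[col] / ref
    return AbundanceMatrix(values=out, stage="scaled", design=design)


def row_zscores(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Row-standardise (mean 0, sd 1 with n-1 denominator) for clustering.

    Rows with fewer than two observed cells are dropped (logged);
    zero-variance rows map to all-zeros by convention.
    """
    matrix.require_stage("normalized", "scaled")
    usable = matrix.values.count(axis=1) >= 2
    dropped = matrix.values.index[~usable]
    if len(dropped):
        logger.info("row_zscores dropped %d rows with <2 values", len(dropped))
    vals = matrix.values.loc[usable]
    mean = vals.mean(axis=1, skipna=True)
    sd = vals.std(axis=1, ddof=1, skipna=True)
    z = vals.sub(mean, axis=0).div(sd.where(sd > 0), axis=0)
    z.loc[sd == 0] = 0.0  # zero-variance convention
    z = z.mask(vals.isna())
    return AbundanceMatrix(values=z, stage="zscore", design=matrix.design)


def _to_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")
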