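"""cBioPortal-dialect multiomics readers, harmonization, and offline fixtures.

The expected on-disk dialect is the tab-delimited gene x sample matrix used
by cBioPortal study downloads: a header row of sample identifiers preceded by
a ``Hugo_Symbol`` column (and optionally ``Entrez_Gene_Id``), one gene per
row.  Copy-number platforms carry the discrete GISTIC codes -2 (homozygous
deletion), -1 (hemizygous deletion), 0 (no change), 1 (gain), 2 (high-level
amplification); expression platforms are continuous (typically z-scored
log values) and methylation platforms take values in (0, 1).

:func:`harmonize` intersects gene sets and sample sets across platforms and
a clinical table carrying nonsynonymous tumor mutational burden (TMB), drops
genes with any missing value on any platform, and emits a ``d x n x p``
:class:`~wdscreen.screening.FeatureArray` with lexicographic gene ordering
(deterministic ordering -> deterministic downstream ranks) plus the matched
TMB response vector.

:func:`make_fixture_cohort` writes a complete synthetic cohort in the same
dialect (mRNA, CNA, methylation, clinical TMB) whose TMB depends on a stated
set of signal genes, so the full selection pipeline can be exercised and
validated offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .screening import FeatureArray

__all__ = [
    "PlatformMatrix",
    "ClinicalTable",
    "OmicsDataError",
    "CNA_CODES",
    "read_platform_matrix",
    "read_clinical",
    "write_platform_matrix",
    "harmonize",
    "save_harmonized",
    "load_harmonized",
    "make_fixture_cohort",
]

logger = logging.getLogger(__name__)

#: legal discrete copy-number codes
CNA_CODES = (-2, -1, 0, 1, 2)

SYMBOL_COLUMN = "Hugo_Symbol"
GENE_ID_COLUMN = "Entrez_Gene_Id"
SAMPLE_ID_COLUMN = "SAMPLE_ID"
DEFAULT_TMB_COLUMN = "TMB_NONSYNONYMOUS"


class OmicsDataError(ValueError):
    """Malformed or inconsistent omics input data."""


@dataclass
class PlatformMatrix:
    """One platform's genes x samples matrix with identifiers."""

    platform_name: str
    gene_symbols: list[str]
    sample_ids: list[str]
    values: np.ndarray  # genes x samples, NaN allowed until harmonization
    gene_ids: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        g, s = self.values.shape
        if len(self.gene_symbols) != g or len(self.sample_ids) != s:
            raise OmicsDataError(
                f"{self.platform_name}: identifier lengths do not match matrix shape"
            )
        if len(set(self.sample_ids)) != s:
            raise OmicsDataError(f"{self.platform_name}: duplicate sample ids")
        if len(set(self.gene_symbols)) != g:
            raise OmicsDataError(
                f"{self.platform_name}: duplicate gene symbols (deduplicate first)"
            )

    def to_frame(self) -> pd.DataFrame:
        data = {SYMBOL_COLUMN: self.gene_symbols}
        if self.gene_ids is not None:
            data[GENE_ID_COLUMN] = self.gene_ids
        frame = pd.DataFrame(data)
        return pd.concat(
            [frame, pd.DataFrame(self.values, columns=self.sample_ids)], axis=1
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical record with the TMB response."""

    sample_ids: list[str]
    tmb: np.ndarray  # NaN = missing; sample dropped at harmonization
    stage: list | None = None

    def __post_init__(self):
        self.tmb = np.asarray(self.tmb, dtype=float)
        if len(self.sample_ids) != self.tmb.size:
            raise OmicsDataError("clinical: sample_ids and tmb lengths differ")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise OmicsDataError("clinical: duplicate sample ids")
        with np.errstate(invalid="ignore"):
            if np.any(self.tmb < 0):
                raise OmicsDataError("clinical: TMB must be nonnegative")


def _validate_cna(symbols: list[str], samples: list[str], values: np.ndarray,
                  platform_name: str) -> None:
    mask = ~np.isnan(values)
    bad = mask & ~np.isin(values, np.asarray(CNA_CODES, dtype=float))
    if np.any(bad):
        g, s = np.argwhere(bad)[0]
        raise OmicsDataError(
            f"{platform_name}: illegal copy-number code {values[g, s]!r} for gene "
            f"{symbols[g]!r}, sample {samples[s]!r} (allowed: {CNA_CODES})"
        )


def read_platform_matrix(path, platform_name: str, *,
                         discrete_codes: bool = False) -> PlatformMatrix:
    """Read one cBioPortal-dialect tab-delimited gene x sample matrix.

    Duplicated gene symbols keep their first occurrence (logged); cells that
    fail numeric parsing become missing, with a logged count.  With
    ``discrete_codes=True`` every non-missing value must be a legal
    copy-number code.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if SYMBOL_COLUMN not in frame.columns:
        raise OmicsDataError(
            f"{path.name}: missing required header column {SYMBOL_COLUMN!r}"
        )
    meta_cols = [SYMBOL_COLUMN] + ([GENE_ID_COLUMN] if GENE_ID_COLUMN in frame else [])
    sample_ids = [c for c in frame.columns if c not in meta_cols]
    if not sample_ids:
        raise OmicsDataError(f"{path.name}: no sample columns found")
    if len(set(sample_ids)) != len(sample_ids):
        raise OmicsDataError(f"{path.name}: duplicate sample columns")
    dup = frame[SYMBOL_COLUMN].duplicated(keep="first")
    if dup.any():
        logger.info("%s: removed %d duplicated gene rows (kept first occurrence)",
                    platform_name, int(dup.sum()))
        frame = frame[~dup]
    raw = frame[sample_ids]
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    coerced = int((values != values).sum() - raw.isna().to_numpy().sum())
    if coerced:
        logger.info("%s: %d unparseable cells treated as missing",
                    platform_name, coerced)
    symbols = frame[SYMBOL_COLUMN].tolist()
    gene_ids = frame[GENE_ID_COLUMN].tolist() if GENE_ID_COLUMN in frame else None
    if discrete_codes:
        _validate_cna(symbols, sample_ids, values, platform_name)
    return PlatformMatrix(platform_name, symbols, sample_ids, values, gene_ids)


def write_platform_matrix(platform: PlatformMatrix, path, *,
                          float_format: str | None = "%.6g") -> None:
    """Write a platform back to the tab-delimited dialect (round-trip safe)."""
    platform.to_frame().to_csv(path, sep="\t", index=False,
                               float_format=float_format)


def read_clinical(path, *, tmb_column: str = DEFAULT_TMB_COLUMN,
                  stage_column: str | None = None) -> ClinicalTable:
    """Read a tab-delimited clinical sample table with a TMB column."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in (SAMPLE_ID_COLUMN, tmb_column):
        if col not in frame.columns:
            raise OmicsDataError(f"{path.name}: missing clinical column {col!r}")
    tmb = pd.to_numeric(frame[tmb_column], errors="coerce").to_numpy(dtype=float)
    stage = frame[stage_column].tolist() if stage_column in frame.columns else None
    return ClinicalTable(frame[SAMPLE_ID_COLUMN].tolist(), tmb, stage)


def harmonize(platforms: list[PlatformMatrix],
              clinical: ClinicalTable) -> tuple[FeatureArray, np.ndarray]:
    """Align platforms and clinical data into (FeatureArray, TMB vector).

    Genes: intersection across platforms, minus any gene with a missing value
    on any platform, ordered lexicographically.  Samples: intersection across
    platforms and the clinical table, restricted to samples with non-missing
    TMB, ordered lexicographically.
    """
    if not platforms:
        raise OmicsDataError("harmonize requires at least one platform")
    genes = set(platforms[0].gene_symbols)
    for pm in platforms[1:]:
        genes &= set(pm.gene_symbols)
    tmb_by_sample = {
        sid: v for sid, v in zip(clinical.sample_ids, clinical.tmb)
        if not np.isnan(v)
    }
    samples = set(tmb_by_sample)
    for pm in platforms:
        samples &= set(pm.sample_ids)
    if not genes or len(samples) < 3:
        detail = "; ".join(
            f"{pm.platform_name}: {len(pm.gene_symbols)} genes x "
            f"{len(pm.sample_ids)} samples" for pm in platforms
        )
        raise OmicsDataError(
            f"empty harmonized intersection ({len(genes)} genes, "
            f"{len(samples)} samples with TMB) — inputs: {detail}"
        )
    gene_order = sorted(genes)
    sample_order = sorted(samples)
    blocks = []
    complete = np.ones(len(gene_order), dtype=bool)
    for pm in platforms:
        gidx = {g: i for i, g in enumerate(pm.gene_symbols)}
        sidx = {s: i for i, s in enumerate(pm.sample_ids)}
        sub = pm.values[np.ix_([gidx[g] for g in gene_order],
                               [sidx[s] for s in sample_order])]
        complete &= ~np.isnan(sub).any(axis=1)
        blocks.append(sub)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("harmonize: dropped %d genes with missing values", dropped)
    gene_final = [g for g, ok in zip(gene_order, complete) if ok]
    if not gene_final:
        raise OmicsDataError("no genes remain after missing-value filtering")
    fa = FeatureArray(
        values=np.stack([b[complete].T for b in blocks]),  # d x n x p
        feature_ids=gene_final,
        sample_ids=sample_order,
        platform_names=[pm.platform_name for pm in platforms],
    )
    tmb = np.array([tmb_by_sample[s] for s in sample_order])
    logger.info("harmonize: %d platforms x %d samples x %d genes",
                fa.n_platforms, fa.n_samples, fa.n_features)
    return fa, tmb


def save_harmonized(fa: FeatureArray, response: np.ndarray, path) -> Path:
    """Persist a harmonized array as compressed binary plus a JSON sidecar.

    Writes ``<path>.npz`` (values + response) and ``<path>.json`` (platform,
    sample and gene identifiers), so downstream runs can skip re-parsing the
    platform matrices.
    """
    import json

    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), values=fa.values,
                        response=np.asarray(response, dtype=float))
    sidecar = {
        "platform_names": fa.platform_names,
        "sample_ids": fa.sample_ids,
        "feature_ids": fa.feature_ids,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar) + "\n")
    return path.with_suffix(".npz")


def load_harmonized(path) -> tuple[FeatureArray, np.ndarray]:
    """Inverse of :func:`save_harmonized`."""
    import json

    path = Path(path)
    with np.load(path.with_suffix(".npz")) as npz:
        values = npz["values"]
        response = npz["response"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    fa = FeatureArray(values, sidecar["feature_ids"], sidecar["sample_ids"],
                      sidecar["platform_names"])
    return fa, response


# ---------------------------------------------------------------------------
# synthetic fixture cohort


FIXTURE_FILES = {
    "mrna": "data_mrna_seq_v2_rsem_zscores_ref_all_samples.txt",
    "cna": "data_cna.txt",
    "methylation": "data_methylation_hm450.txt",
    "clinical": "data_clinical_sample.txt",
}


def make_fixture_cohort(n_samples: int, n_genes: int, signal_genes,
                        seed, outdir) -> dict[str, Path]:
    """Write a synthetic multiomics cohort in the cBioPortal dialect.

    Three platform files (z-scored mRNA, discrete CNA codes, methylation in
    (0, 1)) plus a clinical table with nonsynonymous TMB.  TMB is linear in
    the mRNA of the signal genes with an additional CNA-code effect and unit
    normal noise, so a correctly wired screening pipeline recovers the signal
    genes.  ``signal_genes`` is either a count (genes drawn at random) or an
    explicit list of gene names from the ``G0000 ...`` universe.  Output is
    byte-deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"TCGA-FX-{i:04d}" for i in range(n_samples)]
    if isinstance(signal_genes, (int, np.integer)):
        signal = sorted(rng.choice(genes, size=int(signal_genes), replace=False))
    else:
        signal = sorted(str(g) for g in signal_genes)
        unknown = set(signal) - set(genes)
        if unknown:
            raise OmicsDataError(f"signal genes outside the universe: {sorted(unknown)}")
    sig_idx = [genes.index(g) for g in signal]

    # CNA: discrete codes, mostly neutral
    cna = rng.choice(CNA_CODES, size=(n_genes, n_samples),
                     p=[0.05, 0.2, 0.5, 0.2, 0.05]).astype(float)
    # mRNA: partially driven by copy number, then z-scored per gene
    mrna = 0.6 * cna + rng.standard_normal((n_genes, n_samples))
    mrna = (mrna - mrna.mean(axis=1, keepdims=True)) / mrna.std(axis=1, keepdims=True)
    # methylation: beta-like values, mildly anti-correlated with expression
    # for signal genes (promoter methylation represses transcription)
    meth = rng.beta(2.0, 5.0, size=(n_genes, n_samples))
    meth[sig_idx] = np.clip(meth[sig_idx] - 0.08 * mrna[sig_idx], 1e-4, 1 - 1e-4)

    beta = rng.choice([-1.0, 1.0], size=len(sig_idx)) * rng.uniform(
        1.5, 2.5, size=len(sig_idx)
    )
    gamma = 0.5 * beta
    tmb = 8.0 + beta @ mrna[sig_idx] + gamma @ cna[sig_idx]
    tmb = np.maximum(tmb + rng.standard_normal(n_samples), 0.01)

    written: dict[str, Path] = {}
    specs = [
        ("mrna", mrna, "%.4f"),
        ("cna", cna, "%.0f"),
        ("methylation", meth, "%.4f"),
    ]
    for name, matrix, fmt in specs:
        pm = PlatformMatrix(name, genes, samples, matrix,
                            gene_ids=list(range(1, n_genes + 1)))
        path = outdir / FIXTURE_FILES[name]
        write_platform_matrix(pm, path, float_format=fmt)
        written[name] = path
    clin = pd.DataFrame({SAMPLE_ID_COLUMN: samples,
                         DEFAULT_TMB_COLUMN: [f"{v:.4f}" for v in tmb]})
    clin_path = outdir / FIXTURE_FILES["clinical"]
    clin.to_csv(clin_path, sep="\t", index=False)
    written["clinical"] = clin_path
    manifest = outdir / "signal_genes.txt"
    manifest.write_text("\n".join(signal) + "\n")
    written["signal_genes"] = manifest
    return written
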