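"""Pathway-level meta-analysis across association studies (Meta-MSEA).

Marker-level meta-analysis across platforms, ethnicities or species is
fragile because marker universes rarely align.  Combining instead at the
gene-set level only needs a shared gene-set collection: each study is
analyzed separately with MSEA and the per-study enrichment p-values of a
given set are pooled with an unweighted Stouffer combination,

    z_i = Phi^{-1}(1 - p_i),   z_meta = sum_i z_i / sqrt(k),
    p_meta = 1 - Phi(z_meta),

which reduces exactly to the single-study result at k = 1.  FDR is then
controlled over the meta p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_tables import GeneSetCollection, MarkerAssociation, MarkerGeneMap
from .msea import EnrichmentResult, MseaConfig, benjamini_hochberg, run_msea

log = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class MetaEnrichmentResult:
    """Per-gene-set meta-analysis outcome over k studies."""

    module_id: str
    study_p_values: tuple[float, ...]
    study_statistics: tuple[float, ...]
    meta_z: float
    meta_p: float
    meta_fdr: float
    n_studies: int


def combine_module(p_values: Sequence[float]) -> tuple[float, float]:
    """Unweighted Stouffer combination of one-sided p-values.

    Returns (meta_z, meta_p).  k = 1 returns the input p unchanged.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    # keep the k = 1 reduction exact instead of round-tripping through Phi
    if len(p) == 1:
        return float(stats.norm.isf(p[0])), float(p[0])
    z = stats.norm.isf(np.clip(p, 1e-300, 1 - 1e-16))
    meta_z = float(z.sum() / np.sqrt(len(z)))
    return meta_z, float(np.clip(stats.norm.sf(meta_z), np.nextafter(0, 1), 1.0))


def run_meta_msea(
    studies: Sequence[tuple[MarkerAssociation, MarkerGeneMap]],
    genesets: GeneSetCollection,
    config: MseaConfig | None = None,
    seed: int | None = None,
) -> tuple[list[MetaEnrichmentResult], list[list[EnrichmentResult]]]:
    """MSEA per study on a shared gene-set collection, then Stouffer meta.

    Sets failing the size filter in some studies are combined over the
    studies where they were tested (k adjusted); a set tested nowhere is
    excluded.  Every study is analyzed with the same permutation seed so
    that byte-identical studies yield byte-identical per-study results and
    the analysis is invariant to study order.
    """
    if not studies:
        raise ValueError("at least one study is required")
    config = config or MseaConfig()
    per_study: list[list[EnrichmentResult]] = []
    for i, (assoc, mapping) in enumerate(studies):
        log.info("meta-analysis: study %d of %d", i + 1, len(studies))
        per_study.append(run_msea(assoc, mapping, genesets, config, seed=seed))

    by_module: dict[str, list[tuple[float, float]]] = {}
    for results in per_study:
        for r in results:
            by_module.setdefault(r.module_id, []).append((r.p_value, r.statistic))

    modules = sorted(by_module)
    metas = []
    for module in modules:
        pvals = tuple(p for p, _ in by_module[module])
        zstats = tuple(x for _, x in by_module[module])
        meta_z, meta_p = combine_module(pvals)
        metas.append((module, pvals, zstats, meta_z, meta_p))
    fdr = benjamini_hochberg([m[4] for m in metas])
    out = [
        MetaEnrichmentResult(
            module_id=module,
            study_p_values=pvals,
            study_statistics=zstats,
            meta_z=meta_z,
            meta_p=meta_p,
            meta_fdr=float(q),
            n_studies=len(pvals),
        )
        for (module, pvals, zstats, meta_z, meta_p), q in zip(metas, fdr)
    ]
    out.sort(key=lambda r: (r.meta_p, r.module_id))
    return out, per_study


def write_meta_tables(results: Sequence[MetaEnrichmentResult], out_dir) -> None:
    """Meta-level tables in the MSEA layout (ranked p-value list + full)."""
    import pandas as pd
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(results, key=lambda r: (r.meta_p, r.module_id))
    pd.DataFrame(
        [(r.module_id, r.meta_p, r.meta_fdr) for r in ordered],
        columns=["MODULE", "P", "FDR"],
    ).to_csv(out_dir / "MSEA_modules_pval.txt", sep="\t", index=False,
             float_format="%.6g")
    pd.DataFrame(
        [
            (
                r.module_id,
                r.meta_p,
                r.meta_fdr,
                r.meta_z,
                r.n_studies,
                ",".join(f"{p:.4g}" for p in r.study_p_values),
            )
            for r in ordered
        ],
        columns=["MODULE", "P", "FDR", "META_Z", "N_STUDIES", "STUDY_P"],
    ).to_csv(out_dir / "MSEA_modules_full_results.txt", sep="\t", index=False,
             float_format="%.6g")
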