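"""End-to-end orchestration: catalogue + store -> full report bundle.

One :class:`RunConfig` drives classification, per-population tallies,
prevalence reports and gene summaries, writing a TSV bundle plus a
structured key=value log.  Outputs are written atomically (temp file then
rename) so a crashed run never leaves a truncated table behind.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import yaml

from . import classify as _classify
from .catalogue import (
    ARVC_GENE_META,
    GeneMeta,
    read_catalogue,
    read_gene_meta,
)
from .classify import (
    ClassifiedVariant,
    count_common,
    per_population_tally,
    validate_threshold,
    write_classified_tsv,
)
from .frequencies import (
    DEFAULT_POPULATIONS,
    read_frequency_table,
    read_frequency_vcf,
)
from .gene_summary import (
    count_store_variants,
    presence_summary,
    review_flags,
    write_review_flags,
)
from .prevalence import rule_comparison

__all__ = ["RunConfig", "run_all", "load_config"]


@dataclass
class RunConfig:
    catalogue_path: str
    store_path: str
    out_dir: str
    gene_meta_path: str | None = None  # None -> bundled ARVC gene metadata
    thresholds: Sequence[float] = (0.001, 0.0001)
    populations: Sequence[str] = DEFAULT_POPULATIONS
    include_oth: bool = True
    filter_policy: str = "pass"
    n_individuals: int = 138_632
    seed: int = 0

    def validate(self) -> None:
        if not self.thresholds:
            raise ValueError("thresholds must be non-empty")
        for t in self.thresholds:
            validate_threshold(t)
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")

    @property
    def active_populations(self) -> tuple[str, ...]:
        pops = tuple(self.populations)
        if not self.include_oth:
            pops = tuple(p for p in pops if p != "OTH")
        return pops


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _atomic_write(path: Path, writer: Callable[[Path], None]) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


class StageError(RuntimeError):
    """A hard error, annotated with the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run the pipeline and write the report bundle.

    Outputs in ``out_dir``: ``classified_t<t>.tsv`` per threshold,
    ``tally_t<t>.tsv``, ``prevalence.tsv`` (stacked per-threshold tables),
    ``prevalence_summary.txt``, ``gene_summary.tsv``, ``review_flags.tsv``
    and ``run.log``.  Deterministic for a fixed config.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"thresholds={','.join(str(t) for t in config.thresholds)}",
        f"populations={','.join(config.active_populations)}",
        f"filter_policy={config.filter_policy}",
        f"n_individuals={config.n_individuals}",
    ]
    paths: dict[str, Path] = {}

    def stage(name: str, fn: Callable[[], object]) -> object:
        try:
            return fn()
        except Exception as exc:
            raise StageError(name, exc) from exc

    catalogue = stage("catalogue", lambda: read_catalogue(config.catalogue_path))
    log_lines.append(f"catalogue_records={len(catalogue)}")

    def _read_store() -> list:
        p = str(config.store_path)
        if p.endswith((".vcf", ".vcf.gz", ".bcf")):
            return list(read_frequency_vcf(p, pops=config.active_populations))
        return list(read_frequency_table(p))

    store = stage("store", _read_store)
    log_lines.append(f"store_records={len(store)}")

    if config.gene_meta_path:
        gene_meta: dict[str, GeneMeta] = stage(
            "gene_meta", lambda: read_gene_meta(config.gene_meta_path)
        )
    else:
        gene_meta = dict(ARVC_GENE_META)

    pops = config.active_populations
    classified_by_t: dict[float, list[ClassifiedVariant]] = {}
    for t in config.thresholds:
        classified = stage(
            f"classify_t{t:g}",
            lambda t=t: _classify.classify_all(
                catalogue, store, t=t, pops=pops, filter_policy=config.filter_policy
            ),
        )
        classified_by_t[t] = classified
        p = out / f"classified_t{t:g}.tsv"
        _atomic_write(p, lambda tmp, t=t, c=classified: write_classified_tsv(
            c, tmp, pops=pops,
            params={"threshold": t, "filter_policy": config.filter_policy},
        ))
        paths[f"classified_t{t:g}"] = p
        tally = per_population_tally(classified, t=t, pops=pops)
        tp = out / f"tally_t{t:g}.tsv"
        _atomic_write(tp, lambda tmp, ta=tally: ta.to_csv(tmp, sep="\t"))
        paths[f"tally_t{t:g}"] = tp
        for cls in ("pathogenic", "unknown"):
            n_c, n_m, pct = count_common(classified, rule="popmax", classification=cls)
            log_lines.append(f"common_popmax_{cls}_t{t:g}={n_c}/{n_m} pct={pct}")

    base = classified_by_t[config.thresholds[0]]
    reports = stage("prevalence", lambda: rule_comparison(
        base, gene_meta, config.thresholds, config.n_individuals
    ))
    import pandas as pd

    prevalence_frames = []
    for report in reports:
        frame = report.to_frame()
        frame.insert(0, "threshold", report.threshold)
        prevalence_frames.append(frame)
        log_lines.append(f"prevalence {report.summary_line()}")
        for label, reason in report.excluded:
            log_lines.append(f"excluded variant={label} reason={reason!r}")
    pp = out / "prevalence.tsv"
    _atomic_write(pp, lambda tmp: pd.concat(prevalence_frames).to_csv(tmp, sep="\t", index=False))
    paths["prevalence"] = pp
    sp = out / "prevalence_summary.txt"
    _atomic_write(sp, lambda tmp: tmp.write_text(
        "\n".join(r.summary_line() for r in reports) + "\n"
    ))
    paths["prevalence_summary"] = sp

    store_totals = stage("gene_summary", lambda: count_store_variants(store, gene_meta))
    summary = stage("gene_summary", lambda: presence_summary(
        catalogue, base, store_totals, gene_meta
    ))
    gp = out / "gene_summary.tsv"
    _atomic_write(gp, lambda tmp: summary.to_csv(tmp, sep="\t", index=False))
    paths["gene_summary"] = gp

    flags = stage("review_flags", lambda: review_flags(base))
    fp = out / "review_flags.tsv"
    _atomic_write(fp, lambda tmp: write_review_flags(flags, tmp))
    paths["review_flags"] = fp
    log_lines.append(f"review_flags={len(flags)}")

    lp = out / "run.log"
    _atomic_write(lp, lambda tmp: tmp.write_text("\n".join(log_lines) + "\n"))
    paths["log"] = lp
    return paths
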