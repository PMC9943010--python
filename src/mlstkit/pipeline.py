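"""End-to-end orchestration: simulate → type → stats → cc → mst → screen → report.

Every tabular output is TSV with a fixed column order and a comment header
carrying the tool version, a hash of the run configuration, and the seed, so
reruns are diffable. A JSON manifest lists every file written with its
SHA-256 checksum; rerunning with the same config and inputs reproduces the
checksums byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .clonal_complex import (
    STNode,
    clonal_complexes,
    goeburst_mst,
    mst_edge_frame,
    nodes_from_typing,
)
from .diversity_stats import (
    LocusStats,
    locus_stats,
    locus_stats_frame,
    scheme_summary,
)
from .gene_screen import (
    DEFAULT_COV_THRESHOLD,
    DEFAULT_ID_THRESHOLD,
    GeneRef,
    load_gene_refs,
    screen_assembly,
    st_gene_association,
)
from .scheme_db import MLSTDatabase, SchemeDefinition, load_scheme_definition
from .typer import (
    DEFAULT_MIN_IDENTITY,
    TypingResult,
    read_assembly,
    st_table,
    type_collection,
    typing_table,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    assembly_dir: str
    db_dirs: dict[str, str]  # scheme name -> database directory
    gene_refs: str | None = None
    mode: str = "extend"
    min_identity: float = DEFAULT_MIN_IDENTITY
    id_threshold: float = DEFAULT_ID_THRESHOLD
    cov_threshold: float = DEFAULT_COV_THRESHOLD
    seed: int = 0
    outdir: str = "mlstkit_out"

    def validate(self) -> None:
        if not Path(self.assembly_dir).is_dir():
            raise PipelineError("validate", f"assembly dir missing: {self.assembly_dir}")
        for scheme, d in self.db_dirs.items():
            p = Path(d)
            if not p.is_dir():
                raise PipelineError("validate", f"{scheme}: database dir missing: {d}")
            if not (p / "scheme.yaml").exists():
                raise PipelineError("validate", f"{scheme}: no scheme.yaml in {d}")
        if self.gene_refs is not None and not Path(self.gene_refs).exists():
            raise PipelineError("validate", f"gene reference FASTA missing: {self.gene_refs}")
        if self.mode not in ("strict", "extend"):
            raise PipelineError("validate", f"unknown mode {self.mode!r}")

    def digest(self) -> str:
        # outdir does not affect the science; excluded so reruns to a
        # different directory remain byte-identical
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class SchemeBundle:
    """Per-scheme analysis products."""

    scheme: SchemeDefinition
    results: list[TypingResult]
    locus_stats: list[LocusStats]
    summary: "SchemeSummaryLike"
    complexes: list[set[int]]
    singletons: set[int]
    mst_edges: list


SchemeSummaryLike = object  # diversity_stats.SchemeSummary; kept loose for typing


@dataclass
class ReportBundle:
    config: RunConfig
    schemes: dict[str, SchemeBundle]
    screen_table: pd.DataFrame | None
    screen_summary: pd.DataFrame | None
    flagged_sts: dict[str, list[int]] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)


def load_assemblies(directory: str | Path) -> list[tuple[str, dict[str, str]]]:
    """All FASTA files in a directory, sorted by name for determinism."""
    paths = sorted(Path(directory).glob("*.fasta")) + sorted(Path(directory).glob("*.fa"))
    return [(p.stem, read_assembly(p)) for p in paths]


def analyze_scheme(
    results: list[TypingResult], db: MLSTDatabase
) -> SchemeBundle:
    """Diversity statistics, clonal complexes, and MST for one typed collection."""
    per_locus = []
    for locus in db.scheme.loci:
        seqs = [
            r.calls[locus].hit.sequence
            for r in results
            if r.calls[locus].hit is not None
        ]
        if len(seqs) >= 2:
            per_locus.append(locus_stats(locus, seqs))
    summary = scheme_summary(
        db.scheme.name, [r.st for r in results], per_locus
    )
    st_counts = Counter(r.st for r in results if r.st is not None)
    excluded = [r.strain for r in results if r.st is None]
    if excluded:
        logger.warning(
            "%s: excluding strains with undefined ST from CC/MST: %s",
            db.scheme.name, excluded,
        )
    nodes = nodes_from_typing(db.profiles.profiles, dict(st_counts))
    complexes, singletons = clonal_complexes(nodes)
    edges = goeburst_mst(nodes)
    return SchemeBundle(
        scheme=db.scheme,
        results=results,
        locus_stats=per_locus,
        summary=summary,
        complexes=complexes,
        singletons=singletons,
        mst_edges=edges,
    )


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mlstkit {__version__} config={cfg.digest()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Run every stage and write the full report bundle under ``cfg.outdir``."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    try:
        assemblies = load_assemblies(cfg.assembly_dir)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load", str(exc)) from exc
    if not assemblies:
        logger.warning("no assemblies found in %s", cfg.assembly_dir)

    schemes: dict[str, SchemeBundle] = {}
    st_by_strain_per_scheme: dict[str, dict[str, int | None]] = {}
    for scheme_name, db_dir in cfg.db_dirs.items():
        try:
            scheme = load_scheme_definition(Path(db_dir) / "scheme.yaml")
            db = MLSTDatabase.load(scheme, db_dir)
            results = type_collection(
                assemblies, db, mode=cfg.mode, min_identity=cfg.min_identity
            )
            bundle = analyze_scheme(results, db)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"type:{scheme_name}", str(exc)) from exc
        schemes[scheme_name] = bundle
        st_by_strain_per_scheme[scheme_name] = {r.strain: r.st for r in results}

        sdir = outdir / scheme_name
        sdir.mkdir(exist_ok=True)
        _write_tsv(typing_table(results), sdir / "typing.tsv", cfg)
        _write_tsv(st_table(results), sdir / "st_table.tsv", cfg)
        _write_tsv(
            locus_stats_frame(bundle.locus_stats, scheme_name),
            sdir / "locus_stats.tsv",
            cfg,
        )
        s = bundle.summary
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "scheme": s.scheme,
                        "n_strains": s.n_strains,
                        "n_STs": s.n_STs,
                        "mean_D": s.mean_D,
                        "min_D": s.min_D,
                        "max_D": s.max_D,
                        "mean_dnds": s.mean_dnds,
                        "n_complexes": len(bundle.complexes),
                        "n_singletons": len(bundle.singletons),
                    }
                ]
            ),
            sdir / "scheme_summary.tsv",
            cfg,
        )
        cc_rows = [
            {"st": st, "cc": f"CC{i + 1}"}
            for i, comp in enumerate(bundle.complexes)
            for st in sorted(comp)
        ] + [{"st": st, "cc": "singleton"} for st in sorted(bundle.singletons)]
        _write_tsv(pd.DataFrame(cc_rows, columns=["st", "cc"]), sdir / "clonal_complexes.tsv", cfg)
        _write_tsv(mst_edge_frame(bundle.mst_edges), sdir / "mst_edges.tsv", cfg)
        written += [
            sdir / "typing.tsv", sdir / "st_table.tsv", sdir / "locus_stats.tsv",
            sdir / "scheme_summary.tsv", sdir / "clonal_complexes.tsv",
            sdir / "mst_edges.tsv",
        ]

    screen_table = screen_summary = None
    flagged: dict[str, list[int]] = {}
    if cfg.gene_refs is not None:
        try:
            refs = load_gene_refs(cfg.gene_refs)
            screens = [
                screen_assembly(
                    assembly, refs, strain=strain,
                    id_threshold=cfg.id_threshold, cov_threshold=cfg.cov_threshold,
                )
                for strain, assembly in assemblies
            ]
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("screen", str(exc)) from exc
        screen_rows = [
            {
                "strain": s.strain,
                "gene": g,
                "present": r.present,
                "identity": round(r.identity, 4),
                "coverage": round(r.coverage, 4),
                "contig": r.hit.contig if r.hit else None,
                "start": r.hit.start if r.hit else None,
                "end": r.hit.end if r.hit else None,
                "strand": r.hit.strand if r.hit else None,
            }
            for s in screens
            for g, r in s.genes.items()
        ]
        screen_table = pd.DataFrame(screen_rows)
        _write_tsv(screen_table, outdir / "gene_screen.tsv", cfg)
        written.append(outdir / "gene_screen.tsv")

        for scheme_name, st_by_strain in st_by_strain_per_scheme.items():
            assoc, summary, flagged_sts = st_gene_association(st_by_strain, screens)
            flagged[scheme_name] = flagged_sts
            _write_tsv(assoc, outdir / scheme_name / "st_hut_association.tsv", cfg)
            written.append(outdir / scheme_name / "st_hut_association.tsv")
            screen_summary = summary
        if screen_summary is not None:
            _write_tsv(screen_summary, outdir / "gene_screen_summary.tsv", cfg)
            written.append(outdir / "gene_screen_summary.tsv")

    manifest = {str(p.relative_to(outdir)): _checksum(p) for p in written}
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config": cfg.digest(),
                "seed": cfg.seed,
                "files": manifest,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    logger.info("pipeline: wrote %d files to %s", len(written) + 1, outdir)
    return ReportBundle(
        config=cfg,
        schemes=schemes,
        screen_table=screen_table,
        screen_summary=screen_summary,
        flagged_sts=flagged,
        manifest=manifest,
    )


def report(bundle: ReportBundle) -> str:
    """Human-readable per-scheme summary of a pipeline run."""
    lines = [f"mlstkit {__version__} run report (seed={bundle.config.seed})", ""]
    if not bundle.schemes:
        lines.append("no strains / no schemes analysed")
    for name, sb in bundle.schemes.items():
        s = sb.summary
        lines.append(f"== scheme {name} ==")
        if s.n_strains == 0:
            lines.append("  no strains")
            continue
        lines.append(f"  strains: {s.n_strains}   STs: {s.n_STs}")
        lines.append(
            f"  discriminatory power: mean {s.mean_D:.4f} "
            f"(range {s.min_D:.4f}-{s.max_D:.4f})"
        )
        if s.mean_dnds is not None:
            lines.append(f"  mean dN/dS: {s.mean_dnds:.4f}")
        lines.append(
            f"  clonal complexes: {len(sb.complexes)}   singletons: {len(sb.singletons)}"
        )
        lines.append("  locus  alleles  poly_sites  typing_eff  D")
        for ls in sb.locus_stats:
            eff = f"{ls.typing_efficiency:.3f}" if ls.typing_efficiency else "NA"
            lines.append(
                f"  {ls.locus:<8} {ls.n_alleles:>5} {ls.n_polymorphic_sites:>10} "
                f"{eff:>10} {ls.discriminatory_power:.4f}"
            )
        if name in bundle.flagged_sts:
            flagged = bundle.flagged_sts[name]
            lines.append(
                f"  hut-incapable STs: {flagged if flagged else 'none'}"
            )
        lines.append("")
    if bundle.screen_summary is not None:
        lines.append("== gene screen (strains possessing each gene) ==")
        lines.append(bundle.screen_summary.to_string(index=False))
    return "\n".join(lines)
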