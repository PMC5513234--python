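"""Config-driven end-to-end runner.

Executes the full analysis sequence — region extraction, diversity
summaries, Klee diagrams per region, codon-aware variant characterisation,
and the census comparison when census data are present — on either real
(pre-aligned FASTA + annotation tables) or simulated inputs, writing every
artifact under one output directory with a checksum MANIFEST.

Region concordance between the barcode and the whole alignment is
quantified as the Pearson correlation of the vectorised upper triangles of
the two pairwise p-distance matrices (a numeric stand-in for comparing Klee
panels by eye).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import codome, comparative, diversity, klee, mitogenome, synth
from .errors import ParameterError, PipelineError
from .seqio import (
    AlignedSeqSet,
    GeneTable,
    RegionSpec,
    attach_groups,
    extract_region,
    read_census_table,
    read_fasta,
    read_gene_table,
    read_group_table,
    write_matrix,
    write_tsv,
)

logger = logging.getLogger(__name__)

_STANDARD_REGIONS = ("barcode", "5prime-half", "3prime-half", "whole")


@dataclass
class RunConfig:
    """Validated run configuration (see :func:`load_config`)."""

    outdir: Path
    seed: int = 0
    fasta: Path | None = None
    genes: Path | None = None
    groups: Path | None = None
    census: Path | None = None
    preset: str | None = None
    n: int | None = None
    regions: list[str] = field(default_factory=lambda: ["barcode", "whole"])
    run_klee: bool = True
    run_codome: bool = True
    run_comparative: bool = True

    def __post_init__(self) -> None:
        sim = self.preset is not None
        real = self.fasta is not None
        if sim == real:
            raise ParameterError(
                "config must provide exactly one of: input fasta, simulation preset"
            )
        for r in self.regions:
            if r not in _STANDARD_REGIONS:
                raise ParameterError(
                    f"unknown region {r!r}; expected one of {_STANDARD_REGIONS}"
                )


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    inp = raw.get("input", {}) or {}
    sim = raw.get("simulate", {}) or {}
    modules = raw.get("modules", {}) or {}
    return RunConfig(
        outdir=Path(raw.get("outdir", "barcodevar-out")),
        seed=int(raw.get("seed", 0)),
        fasta=Path(inp["fasta"]) if "fasta" in inp else None,
        genes=Path(inp["genes"]) if "genes" in inp else None,
        groups=Path(inp["groups"]) if "groups" in inp else None,
        census=Path(inp["census"]) if "census" in inp else None,
        preset=sim.get("preset"),
        n=sim.get("n"),
        regions=list(raw.get("regions", ["barcode", "whole"])),
        run_klee=bool(modules.get("klee", True)),
        run_codome=bool(modules.get("codome", True)),
        run_comparative=bool(modules.get("comparative", True)),
    )


def _resolve_region(
    name: str, s: AlignedSeqSet, genes: GeneTable | None
) -> RegionSpec:
    if name == "whole":
        return RegionSpec("whole", 1, s.length)
    if name in ("5prime-half", "3prime-half"):
        return mitogenome.half_regions(s.length)[name]
    if name == "barcode":
        if genes is not None:
            return mitogenome.default_barcode(genes)
        return mitogenome.RCRS_REGIONS["COI-barcode"]
    raise ParameterError(f"unknown region {name!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the pipeline; returns a map of artifact name -> path.

    Any stage failure raises :class:`PipelineError` naming the stage; files
    written before the failure are kept and listed in MANIFEST.tsv with an
    ``incomplete`` marker row.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "load-inputs"
    try:
        genes: GeneTable | None = None
        census = None
        if config.preset is not None:
            stage = "simulate"
            p = synth.preset(config.preset, n=config.n, seed=config.seed)
            if isinstance(p, list):  # bird-grid
                raise ParameterError(
                    "bird-grid preset is for the comparative CLI, not `run`"
                )
            sim = synth.simulate_set(p)
            seqs, genes = sim.seqs, sim.genes
            synth.write_sim(sim, out / "simulated")
            for key, suffix in (
                ("sim_fasta", ".fasta"),
                ("sim_genes", ".genes.tsv"),
                ("sim_groups", ".groups.tsv"),
                ("sim_truth", ".truth.tsv"),
            ):
                artifacts[key] = out / f"simulated{suffix}"
        else:
            seqs = read_fasta(config.fasta)
            if config.groups is not None:
                seqs = attach_groups(seqs, read_group_table(config.groups))
            if config.genes is not None:
                genes = read_gene_table(config.genes)
            if config.census is not None:
                census = read_census_table(config.census)

        # per-region diversity + Klee
        for region_name in config.regions:
            stage = f"extract:{region_name}"
            region = _resolve_region(region_name, seqs, genes)
            sub = extract_region(seqs, region)
            stage = f"diversity:{region_name}"
            rows = []
            labels = sub.group_labels() or [None]
            for g in labels:
                idx = (
                    sub.group_members(g) if g is not None else list(range(len(sub)))
                )
                if len(idx) < 2:
                    logger.warning("group %r singleton in %s; skipped", g, region_name)
                    continue
                a, comp = diversity.apd_with_sites(sub, g)
                rows.append(
                    {
                        "group": g if g is not None else "all",
                        "n": len(idx),
                        "APD_percent": f"{a:.6g}",
                        "mean_comparable_sites": f"{comp:.6g}",
                    }
                )
            path = out / f"apd.{region_name}.tsv"
            write_tsv(rows, path)
            artifacts[f"apd:{region_name}"] = path
            if config.run_klee:
                stage = f"klee:{region_name}"
                kr = klee.klee_diagram(sub)
                paths = klee.render_klee(kr, out / f"klee.{region_name}")
                for kind, pth in paths.items():
                    artifacts[f"klee:{region_name}:{kind}"] = pth

        # region concordance: barcode vs whole distance matrices
        stage = "concordance"
        if "barcode" in config.regions:
            region = _resolve_region("barcode", seqs, genes)
            db = diversity.pdistance_matrix(extract_region(seqs, region))
            dw = diversity.pdistance_matrix(seqs)
            iu = np.triu_indices(len(seqs), k=1)
            vb, vw = db[iu], dw[iu]
            if vb.std() > 0 and vw.std() > 0:
                r = float(np.corrcoef(vb, vw)[0, 1])
            else:
                r = float("nan")
            path = out / "concordance.tsv"
            write_tsv(
                [
                    {
                        "comparison": "barcode-vs-whole",
                        "pearson_r": f"{r:.6g}",
                        "n_pairs": len(vb),
                    }
                ],
                path,
            )
            artifacts["concordance"] = path

        # codon-aware characterisation
        if config.run_codome and genes is not None:
            stage = "codome"
            sites = codome.call_variant_sites(seqs, genes)
            write_tsv(
                [
                    {
                        "column": v.column,
                        "gene": v.gene or "",
                        "codon_index": v.codon_index or "",
                        "codon_pos": v.codon_pos or "",
                        "alleles": ",".join(
                            f"{b}:{c}" for b, c in sorted(v.alleles.items())
                        ),
                        "class": v.classification,
                    }
                    for v in sites
                ],
                out / "variants.tsv",
            )
            artifacts["variants"] = out / "variants.tsv"
            report_lines = []
            genic = [v for v in sites if v.gene is not None]
            if genic:
                chi2, df, pval = codome.evenness_test(sites, genes)
                write_tsv(
                    [{"chi2": f"{chi2:.6g}", "df": df, "p": f"{pval:.6g}"}],
                    out / "evenness.tsv",
                )
                artifacts["evenness"] = out / "evenness.tsv"
                report_lines.append(
                    f"evenness: chi2={chi2:.4g} df={df} p={pval:.4g}"
                )
                frac = codome.variant_codon_fraction(sites, genes)
                report_lines.append(f"variant_codon_fraction: {frac:.6g}")
                counts = codome.classification_counts(sites)
                report_lines.append(f"classification_counts: {counts}")
            barcode = _resolve_region("barcode", seqs, genes)
            if barcode.width <= seqs.length:
                rep = codome.representativeness(seqs, barcode)
                write_tsv(
                    [
                        {"window_start": st, "APD_percent": f"{a:.6g}"}
                        for st, a in zip(
                            rep.profile.starts, rep.profile.apd_percent
                        )
                    ],
                    out / "windows.tsv",
                )
                artifacts["windows"] = out / "windows.tsv"
                report_lines += [
                    f"barcode_apd_percent: {rep.barcode_apd:.6g}",
                    f"codome_apd_percent: {rep.codome_apd:.6g}",
                    f"barcode_codome_ratio: {rep.ratio:.6g}",
                    f"barcode_percentile: {rep.percentile:.6g}",
                ]
            (out / "report.txt").write_text("\n".join(report_lines) + "\n")
            artifacts["report"] = out / "report.txt"

        # census comparison
        if config.run_comparative and census:
            stage = "comparative"
            records = comparative.build_table(seqs, census)
            write_tsv(
                [
                    {
                        "species": r.species,
                        "n": r.n,
                        "APD_percent": f"{r.apd_percent:.6g}",
                        "census": f"{r.census:.6g}",
                    }
                    for r in records
                ],
                out / "species_table.tsv",
            )
            artifacts["species_table"] = out / "species_table.tsv"
            if len(records) >= 3:
                rho, pval = comparative.rank_correlation(records)
                (out / "correlation.txt").write_text(
                    f"spearman_rho\t{rho:.6g}\np_two_sided\t{pval:.6g}\n"
                )
                artifacts["correlation"] = out / "correlation.txt"
    except Exception as exc:
        _write_manifest(out, artifacts, incomplete=stage)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    artifacts["manifest"] = _write_manifest(out, artifacts)
    return artifacts


def _write_manifest(
    out: Path, artifacts: dict[str, Path], incomplete: str | None = None
) -> Path:
    rows = [
        {
            "artifact": key,
            "file": str(p.relative_to(out)),
            "sha256": _sha256(p),
            "bytes": p.stat().st_size,
        }
        for key, p in sorted(artifacts.items())
        if p.exists()
    ]
    if incomplete is not None:
        rows.append(
            {
                "artifact": "__incomplete__",
                "file": incomplete,
                "sha256": "",
                "bytes": 0,
            }
        )
    path = out / "MANIFEST.tsv"
    write_tsv(rows, path)
    return path
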