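"""Table readers/writers, configuration, and the end-to-end pipeline.

TSV dialect: tab-separated, '#'-prefixed header comment lines, '.' for
missing values.  All user-facing coordinates are 1-based inclusive; internal
coordinates are 0-based half-open.  VCF input is read-only (mutant and
reference read counts taken from the AD format field).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cna import CnaSegment, analyze_sample_cnas
from .methylation import (associate_probes, bonferroni_threshold,
                          enrichment_by_category)
from .signatures import summarize_sample
from .snv import SomaticSnv, call_clonality, fsm_by_unit
from .synthetic import SimulationConfig, simulate_cohort, simulate_methylation_dataset

logger = logging.getLogger(__name__)

MISSING = "."
MUTATION_COLUMNS = ("chrom", "pos", "ref", "alt", "t_ref_count", "t_alt_count")


class SchemaError(ValueError):
    """An input table is missing a required column or violates an invariant."""


# ---------------------------------------------------------------------------
# Coordinate conversion (user-facing 1-based inclusive <-> internal 0-based
# half-open)
# ---------------------------------------------------------------------------

def pos_to_internal(pos_1based: int) -> int:
    return pos_1based - 1


def pos_to_file(pos_0based: int) -> int:
    return pos_0based + 1


def interval_to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    return start_1based - 1, end_inclusive


def interval_to_file(start_0based: int, end_exclusive: int) -> tuple[int, int]:
    return start_0based + 1, end_exclusive


# ---------------------------------------------------------------------------
# TSV primitives
# ---------------------------------------------------------------------------

def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING])


def write_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Atomic TSV write: the file appears complete or not at all."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False, na_rep=MISSING)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

def read_mutations(path, reference=None) -> list[SomaticSnv]:
    """Read somatic mutations from a MAF-like TSV (or a VCF by extension).

    Required TSV columns: chrom, pos (1-based), ref, alt, t_ref_count,
    t_alt_count.  Optional: sample, gene, consequence, context.  When a
    ``reference`` FASTA (pyfaidx-openable) is given and the context column is
    absent, the trinucleotide context is looked up; records whose ref base
    disagrees with the reference are skipped with a warning.
    """
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_mutations_vcf(path, reference=reference)
    df = read_tsv(path)
    for col in MUTATION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mutation table is missing required column {col!r}")

    fasta = _open_fasta(reference) if reference is not None else None
    out = []
    for row in df.itertuples(index=False):
        ref_count, alt_count = int(row.t_ref_count), int(row.t_alt_count)
        depth = ref_count + alt_count
        if alt_count < 0 or ref_count < 0:
            raise SchemaError(f"negative read count at {row.chrom}:{row.pos}")
        pos0 = pos_to_internal(int(row.pos))
        context = str(getattr(row, "context", "") or "")
        if fasta is not None:
            ref_base = str(fasta[str(row.chrom)][pos0]).upper()
            if ref_base != str(row.ref).upper():
                warnings.warn(
                    f"ref mismatch at {row.chrom}:{row.pos} "
                    f"(file {row.ref}, reference {ref_base}); record skipped")
                continue
            if not context:
                context = str(fasta[str(row.chrom)][pos0 - 1:pos0 + 2]).upper()
        out.append(SomaticSnv(
            chrom=str(row.chrom), pos=pos0, ref=str(row.ref), alt=str(row.alt),
            depth=depth, alt_count=alt_count,
            sample=str(getattr(row, "sample", "") or ""),
            gene=str(getattr(row, "gene", "") or ""),
            consequence=str(getattr(row, "consequence", "") or "other"),
            context=context,
        ))
    return out


def read_mutations_vcf(path, reference=None) -> list[SomaticSnv]:
    """Read SNVs from a VCF, mapping the first sample's AD to (ref, alt) counts."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.ref) != 1:
                continue
            alt = rec.alts[0]
            if len(alt) != 1:
                continue
            sample = next(iter(rec.samples.values()))
            ad = sample.get("AD")
            if ad is None or len(ad) < 2:
                continue
            ref_count, alt_count = int(ad[0]), int(ad[1])
            out.append(SomaticSnv(
                chrom=rec.chrom, pos=rec.pos - 1, ref=rec.ref, alt=alt,
                depth=ref_count + alt_count, alt_count=alt_count,
                sample=next(iter(rec.samples.keys()), ""),
            ))
    return out


def _open_fasta(reference):
    from pyfaidx import Fasta
    return reference if not isinstance(reference, (str, Path)) else Fasta(str(reference))


def write_mutations(snvs: list[SomaticSnv], path) -> None:
    rows = []
    for s in snvs:
        rows.append({
            "sample": s.sample or MISSING, "chrom": s.chrom,
            "pos": pos_to_file(s.pos), "ref": s.ref, "alt": s.alt,
            "t_ref_count": s.depth - s.alt_count, "t_alt_count": s.alt_count,
            "gene": s.gene or MISSING, "consequence": s.consequence,
            "context": s.context or MISSING, "segment_state": s.segment_state,
            "beta": s.beta, "allele_config": s.allele_config,
            "expected_maf": s.expected_maf, "p_clonal": s.p_clonal,
            "clonality": s.clonality,
        })
    write_tsv(pd.DataFrame(rows), path, header_comment="coordinates: pos is 1-based")


# ---------------------------------------------------------------------------
# Segments and probes
# ---------------------------------------------------------------------------

def read_segments(path) -> list[CnaSegment]:
    """Read CNA segments from a BED-like TSV (1-based inclusive coordinates)."""
    df = read_tsv(path)
    for col in ("chrom", "start", "end", "state"):
        if col not in df.columns:
            raise SchemaError(f"segment table is missing required column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        start0, end_excl = interval_to_internal(int(row.start), int(row.end))
        ratio = getattr(row, "read_ratio", None)
        seg = CnaSegment(
            chrom=str(row.chrom), start=start0, end=end_excl, state=str(row.state),
            sample=str(getattr(row, "sample", "") or ""),
            read_ratio=None if ratio is None or pd.isna(ratio) else float(ratio),
        )
        for col in ("mu1", "mu2", "cell_fraction"):
            v = getattr(row, col, None)
            if v is not None and not pd.isna(v):
                setattr(seg, "cell_fraction_c" if col == "cell_fraction" else col, float(v))
        if "clonality" in df.columns and not pd.isna(row.clonality):
            seg.clonality = str(row.clonality)
        out.append(seg)
    return out


def write_segments(segments: list[CnaSegment], path) -> None:
    rows = []
    for s in segments:
        start1, end1 = interval_to_file(s.start, s.end)
        rows.append({
            "sample": s.sample or MISSING, "chrom": s.chrom, "start": start1,
            "end": end1, "state": s.state, "read_ratio": s.read_ratio,
            "mu1": s.mu1, "mu2": s.mu2, "cell_fraction": s.cell_fraction_c,
            "clonality": s.clonality,
        })
    write_tsv(pd.DataFrame(rows), path,
              header_comment="coordinates: start/end are 1-based inclusive")


def write_probes(samples, path) -> None:
    rows = []
    for ts in samples:
        for seg in ts.segments:
            if seg.baf_values is None:
                continue
            positions = np.linspace(seg.start, seg.end - 1, len(seg.baf_values)).astype(int)
            for pos, baf in zip(positions, seg.baf_values):
                rows.append({"sample": ts.sample, "chrom": seg.chrom,
                             "pos": pos_to_file(int(pos)), "baf": round(float(baf), 6),
                             "lrr": MISSING})
    write_tsv(pd.DataFrame(rows), path, header_comment="coordinates: pos is 1-based")


def attach_probes_to_segments(segments: list[CnaSegment], probes: pd.DataFrame) -> None:
    """Assign each probe's BAF to the segment containing it (per sample)."""
    for seg in segments:
        sel = probes[
            ((probes["sample"] == seg.sample) if "sample" in probes.columns else True)
            & (probes["chrom"] == seg.chrom)
            & (probes["pos"] - 1 >= seg.start)
            & (probes["pos"] - 1 < seg.end)
        ]
        seg.baf_values = sel["baf"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    out_dir: str = "clonescape_out"
    seed: int = 0
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    clonality_cutoff: float = 0.05
    rel_tol: float = 0.2
    bonferroni_alpha: float = 0.05
    target_mb: float = 30.0           # exome footprint for rates per Mb
    meth_samples: int = 200
    meth_probes: int = 2000
    meth_assoc: int = 40
    meth_effect_size: float = 0.05
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        for key in ("purity_range", "beta_range", "subclonal_ccf_range"):
            v = getattr(sim, key)
            if isinstance(v, list):
                setattr(sim, key, tuple(v))
        cfg = cls(simulation=sim, **raw)
        cfg.simulation.seed = cfg.seed if "seed" in raw else cfg.simulation.seed
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> purity -> snv-clonality -> signatures -> meth-assoc.

    Writes all stage tables plus a manifest under ``config.out_dir`` and
    returns the manifest dict.  Reruns with the same config and seed produce
    byte-identical numeric outputs.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = dataclasses.replace(config.simulation, seed=config.seed)
    samples, truths = simulate_cohort(sim)
    write_probes(samples, out / "probes.tsv")

    purity_rows = []
    all_segments = []
    all_snvs = []
    summaries = []
    for ts, truth in zip(samples, truths):
        purity = analyze_sample_cnas(ts.segments, rel_tol=config.rel_tol)
        ts.purity = purity.alpha
        purity_rows.append({"sample": ts.sample, "alpha": purity.alpha,
                            "n_peaks": len(purity.density_peaks)})
        for snv in ts.snvs:
            # beta among tumor cells relative to the *estimated* purity
            seg_c = next(
                (s.cell_fraction_c for s in ts.segments
                 if s.chrom == snv.chrom and s.start <= snv.pos < s.end
                 and s.cell_fraction_c is not None), None)
            if snv.segment_state in ("CN1", "LOH") and seg_c is not None:
                snv.beta = float(np.clip(seg_c / purity.alpha, 0.0, 1.0))
            call_clonality(snv, purity.alpha, alpha_cutoff=config.clonality_cutoff)
        summaries.append(summarize_sample(ts.snvs, config.target_mb, sample=ts.sample))
        all_segments.extend(ts.segments)
        all_snvs.extend(ts.snvs)

    write_segments(all_segments, out / "segments_annotated.tsv")
    write_mutations(all_snvs, out / "mutations_annotated.tsv")
    write_tsv(pd.DataFrame(purity_rows), out / "purity.tsv")
    write_tsv(pd.DataFrame([{"sample": t.sample, "alpha": t.alpha} for t in truths]),
              out / "truth_purity.tsv")

    sig_rows = []
    for s in summaries:
        row = {"sample": s.sample, "tnsm": s.tnsm, "ft": s.ft, "fa": s.fa,
               "rate_per_mb": s.rate_per_mb}
        row.update(s.fractions)
        sig_rows.append(row)
    write_tsv(pd.DataFrame(sig_rows), out / "signatures.tsv")

    gene_fsm = fsm_by_unit(all_snvs, key=lambda s: s.gene)
    write_tsv(pd.DataFrame([dataclasses.asdict(g) for g in gene_fsm]),
              out / "fsm_by_gene.tsv")

    meth = simulate_methylation_dataset(
        n_samples=config.meth_samples, n_probes=config.meth_probes,
        n_assoc=config.meth_assoc, effect_size=config.meth_effect_size,
        seed=config.seed + 1,
    )
    assoc = associate_probes(meth.methylation, meth.trait, meth.covariates,
                             trait_name="TNSM", annotations=meth.annotations)
    threshold = bonferroni_threshold(len(assoc), config.bonferroni_alpha)
    assoc["significant"] = assoc["p"] < threshold
    write_tsv(assoc, out / "meth_associations.tsv")
    enr = enrichment_by_category(assoc, threshold)
    write_tsv(pd.DataFrame([dataclasses.asdict(e) for e in enr]),
              out / "meth_enrichment.tsv")

    manifest = {
        "package": "clonescape",
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in dataclasses.asdict(config).items()},
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
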