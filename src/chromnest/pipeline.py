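"""End-to-end orchestration: balance -> sweep -> domains -> nestedness ->
optional folding-model fit and chromatin enrichment, with a reproducible
manifest (config echo, seeds, stage output checksums)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .chromatin_enrichment import ChromatinTrack, enrich_communities
from .community_detection import default_gamma_grid, fg_null, gamma_sweep
from .contact_data import kr_balance, load_contact_matrix
from .domain_extraction import build_membership, domains_to_bed, extract_domains, folding_pathways
from .folding_model import domain_interaction, fit_q
from .nestedness import nestedness_summary, pairwise_nestedness, records_to_tsv
from .synthetic import SyntheticSpec, synth_contact_matrix, synth_hierarchy

logger = logging.getLogger("chromnest")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``contact_path``+``contact_format`` point at real input, or
    ``synthetic`` carries a generator spec (self-contained mode).
    """

    output_dir: str = "chromnest_run"
    contact_path: str | None = None
    contact_format: str = "dense-tsv"
    chrom: str = "chrN"
    bin_size: int = 100_000
    synthetic: dict | None = None
    gamma_grid: list = field(default_factory=lambda: list(default_gamma_grid()))
    decay_exponent: float = 1.0
    restarts: int = 10
    nestedness_threshold: float = 0.025
    enrichment_fdr: float = 0.05
    chromatin_path: str | None = None
    fit_model: bool = False
    q_grid: list = field(default_factory=lambda: list(np.round(np.arange(0, 1.0001, 0.05), 3)))
    q_replicates: int = 20
    model_rings: int = 5
    balance: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.gamma_grid:
            raise ValueError("gamma grid must be nonempty")
        for name, v in [
            ("nestedness_threshold", self.nestedness_threshold),
            ("enrichment_fdr", self.enrichment_fdr),
        ]:
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.contact_path is None and self.synthetic is None:
            raise ValueError("either contact_path or synthetic spec required")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns (and writes) the run manifest.

    Outputs land in ``config.output_dir``; a failure renames the directory
    contents under a ``failed/`` marker and re-raises with the stage name.
    Re-running an identical config reproduces byte-identical outputs.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "chromnest",
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }
    stage = "setup"
    try:
        t0 = time.time()
        stage = "load"
        if config.synthetic is not None:
            spec = SyntheticSpec(**{**config.synthetic, "seed": config.seed})
            hierarchy = synth_hierarchy(spec)
            matrix = synth_contact_matrix(spec, hierarchy)
        else:
            matrix = load_contact_matrix(
                config.contact_path,
                format=config.contact_format,
                chrom=config.chrom,
                bin_size=config.bin_size,
            )
        logger.info("loaded %d bins (%.1fs)", matrix.n_bins, time.time() - t0)

        if config.balance:
            stage = "balance"
            t0 = time.time()
            matrix = kr_balance(matrix).scaled
            logger.info("balanced (%.1fs)", time.time() - t0)

        stage = "communities"
        t0 = time.time()
        null = fg_null(matrix, exponent=config.decay_exponent)
        ps = gamma_sweep(
            matrix, config.gamma_grid, seed=config.seed, restarts=config.restarts, null=null
        )
        import pandas as pd

        part_rows = []
        for part in ps:
            for b, c in enumerate(part.membership):
                part_rows.append(
                    (matrix.chrom, b * matrix.bin_size, (b + 1) * matrix.bin_size, part.gamma, c)
                )
        pd.DataFrame(
            part_rows, columns=["chrom", "start", "end", "gamma", "community_id"]
        ).to_csv(out / "partitions.tsv", sep="\t", index=False)
        with open(out / "partitions.json", "w") as fh:
            json.dump(
                {str(p.gamma): p.membership.tolist() for p in ps}, fh, separators=(",", ":")
            )
        logger.info("sweep over %d gammas (%.1fs)", len(ps), time.time() - t0)

        stage = "domains"
        domains = extract_domains(ps)
        domains_to_bed(domains, matrix.chrom, matrix.bin_size, out / "domains.bed")
        mt = build_membership(ps, domains)
        mt.to_tsv(out / "membership.tsv")
        if len(ps) >= 2:
            with open(out / "pathways.json", "w") as fh:
                json.dump(folding_pathways(mt), fh, indent=1)

        stage = "nestedness"
        t0 = time.time()
        records = pairwise_nestedness(mt, threshold=config.nestedness_threshold)
        records_to_tsv(records, out / "nestedness.tsv")
        summary = nestedness_summary(records)
        with open(out / "nestedness_summary.json", "w") as fh:
            json.dump(
                {
                    k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in summary.items()
                },
                fh,
                indent=1,
            )
        logger.info("%d overlap records (%.1fs)", len(records), time.time() - t0)

        if config.fit_model:
            stage = "model"
            t0 = time.time()
            strengths = domain_interaction(matrix, domains)
            sizes = np.array([d.n_bins for d in domains], dtype=float)
            fit = fit_q(
                records,
                strengths,
                q_grid=np.asarray(config.q_grid, dtype=float),
                replicates=config.q_replicates,
                seed=config.seed,
                n_rings=config.model_rings,
                sizes=sizes,
            )
            with open(out / "q_fit.json", "w") as fh:
                json.dump(
                    {
                        "q_grid": fit.q_grid.tolist(),
                        "mean_ks_distance": fit.distances.tolist(),
                        "q_opt": fit.q_opt,
                        "replicates": fit.replicates,
                        "seed": fit.seed,
                    },
                    fh,
                    indent=1,
                )
            pd.DataFrame({"Q": fit.q_grid, "mean_ks_distance": fit.distances}).to_csv(
                out / "q_fit.tsv", sep="\t", index=False
            )
            logger.info("Q fit -> %.2f (%.1fs)", fit.q_opt, time.time() - t0)

        if config.chromatin_path is not None:
            stage = "enrichment"
            track = ChromatinTrack.from_bed(config.chromatin_path)
            erecs, labels = enrich_communities(
                track, mt, domains, matrix.bin_size, fdr=config.enrichment_fdr
            )
            pd.DataFrame([vars(r) for r in erecs]).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                [
                    {
                        "gamma": l.gamma,
                        "community": l.community,
                        "groups": "".join(sorted(l.groups)),
                        "degenerate": l.degenerate,
                    }
                    for l in labels
                ]
            ).to_csv(out / "group_labels.tsv", sep="\t", index=False)

        stage = "manifest"
        for f in sorted(out.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                manifest["stages"][f.name] = _sha256(f)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return manifest
    except Exception as exc:
        marker = out / "failed"
        marker.mkdir(exist_ok=True)
        (marker / "stage.txt").write_text(f"{stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
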