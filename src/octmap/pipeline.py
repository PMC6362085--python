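"""End-to-end orchestration: preprocess -> distances -> embedding -> outputs.

A :class:`PipelineConfig` holds every tunable of the chain; a run writes
the distance matrix, mapped coordinates and a JSON manifest (config hash,
seeds, per-stage counts) into the output directory. Reruns with the same
config and inputs reproduce the coordinates bit-identically (the only
stochastic stage, t-SNE, is seeded).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as _io
from .distance import pairwise_distance_matrix
from .embed import isomap_embed, residual_variance, tsne_embed
from .preprocess import DEFAULT_MEDIAN_WINDOW_MM, ImagePreprocessor

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Defaults follow the instrument frame (15.625 x 31.25 um pixels) and the
    0.055 mm x 0.117 mm median window; embedding defaults (k = 12,
    perplexity = 30, seed = 0) are package choices.
    """

    px_mm_x: float = 16.0 / 1024
    px_mm_y: float = 8.0 / 256
    median_window_mm: tuple[float, float] = DEFAULT_MEDIAN_WINDOW_MM
    diffusion_n_iter: int = 15
    diffusion_kappa: float = 0.1
    diffusion_lam: float = 0.25
    metric: str = "hellinger"
    method: str = "tsne"
    isomap_k: int = 12
    perplexity: float = 30.0
    seed: int = 0
    grid_shape: tuple[int, int] = (8, 12)
    out_dir: str = "octmap_out"
    save_canvases: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.median_window_mm = tuple(cfg.median_window_mm)
        cfg.grid_shape = tuple(cfg.grid_shape)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["median_window_mm"] = list(self.median_window_mm)
        d["grid_shape"] = list(self.grid_shape)
        return d

    def digest(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, input_dir=None,
                 images=None) -> dict:
    """Run the full chain on a directory of images (or in-memory images).

    Returns the run manifest; artifacts (``D.csv``, ``coords.csv``,
    ``manifest.json``, optionally aligned canvases) are written under
    ``config.out_dir``.
    """
    if images is None:
        if input_dir is None:
            raise ValueError("provide input_dir or images")
        images = _io.read_image_dir(input_dir, config.px_mm_x, config.px_mm_y)
    if len(images) == 0:
        raise ValueError("no input images: nothing to do")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"config": config.as_dict(), "config_hash": config.digest(),
                      "n_images": len(images), "stages": {}}

    t0 = time.perf_counter()
    pre = ImagePreprocessor(median_window_mm=config.median_window_mm,
                            diffusion_n_iter=config.diffusion_n_iter,
                            diffusion_kappa=config.diffusion_kappa,
                            diffusion_lam=config.diffusion_lam)
    try:
        aligned = pre.fit_transform(images)
    except Exception as exc:
        raise RuntimeError(f"stage preprocess failed: {exc}") from exc
    manifest["stages"]["preprocess"] = {"n_aligned": len(aligned),
                                        "seconds": round(time.perf_counter() - t0, 3)}
    logger.info("preprocess: %d canvases in %.1fs", len(aligned),
                time.perf_counter() - t0)
    if config.save_canvases:
        cdir = out / "aligned"
        cdir.mkdir(exist_ok=True)
        for a in aligned:
            _io.write_tiff16(cdir / f"{a.source_id}.tiff", a.canvas)

    t0 = time.perf_counter()
    try:
        dmat = pairwise_distance_matrix(aligned, metric=config.metric)
    except Exception as exc:
        raise RuntimeError(f"stage distance failed: {exc}") from exc
    dmat.to_csv(out / "D.csv")
    manifest["stages"]["distance"] = {
        "metric": config.metric, "n": dmat.n,
        "n_pair_evaluations": dmat.n_pair_evaluations,
        "seconds": round(time.perf_counter() - t0, 3)}
    logger.info("distance: %d pairs in %.1fs", dmat.n_pair_evaluations,
                time.perf_counter() - t0)

    t0 = time.perf_counter()
    try:
        if config.method == "isomap":
            emb = isomap_embed(dmat, k=config.isomap_k)
        elif config.method == "tsne":
            emb = tsne_embed(dmat, perplexity=config.perplexity,
                             seed=config.seed)
        else:
            raise ValueError(f"unknown embedding method {config.method!r}")
    except Exception as exc:
        raise RuntimeError(f"stage embed failed: {exc}") from exc
    emb.to_csv(out / "coords.csv")
    manifest["stages"]["embed"] = {
        "method": config.method, "params": emb.params,
        "n_points": emb.n,
        "residual_variance": residual_variance(dmat, emb),
        "seconds": round(time.perf_counter() - t0, 3)}
    logger.info("embed (%s): %d points in %.1fs", config.method, emb.n,
                time.perf_counter() - t0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    config.to_yaml(out / "config.yaml")
    return manifest
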