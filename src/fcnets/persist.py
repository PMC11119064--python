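"""Model checkpoints: portable ``.npz`` arrays + a YAML header.

The ``.npz`` holds every parameter (and batch-norm running statistic); the
``.yaml`` sidecar records the architecture metadata and config needed to
rebuild the container, plus the training seed.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .gan import DiscriminatorParams, GANConfig, GeneratorParams
from .gcn import GCNConfig, GCNModel

__all__ = ["save_gcn", "load_gcn", "save_gan", "load_gan",
           "save_brainnetcnn", "load_brainnetcnn"]


def _write(path: Path, arrays: dict[str, np.ndarray], header: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(header, fh, sort_keys=True)


def _read(path: Path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    with open(path.with_suffix(".yaml")) as fh:
        header = yaml.safe_load(fh)
    return arrays, header


def save_gcn(model: GCNModel, path: str | Path) -> None:
    header = {
        "model": "gcn",
        "n_nodes": model.n_nodes,
        "phen_len": model.phen_len,
        "n_classes": model.n_classes,
        "config": {**asdict(model.cfg),
                   "feature_dims": list(model.cfg.feature_dims)},
    }
    _write(Path(path), model.state_dict(), header)


def load_gcn(path: str | Path) -> GCNModel:
    arrays, header = _read(Path(path))
    cfg = GCNConfig(**header["config"])
    model = GCNModel(header["n_nodes"], header["phen_len"], header["n_classes"],
                     cfg, np.random.default_rng(0))
    model.load_state_dict(arrays)
    return model


def _gan_header(kind: str, n_regions: int, phen_len: int, n_classes: int,
                cfg: GANConfig) -> dict:
    return {"model": kind, "n_regions": n_regions, "phen_len": phen_len,
            "n_classes": n_classes, "config": asdict(cfg)}


def save_gan(gen: GeneratorParams, disc: DiscriminatorParams,
             path: str | Path) -> None:
    arrays = {f"gen_{k}": v for k, v in gen.state_dict().items()}
    arrays.update({f"disc_{k}": v for k, v in disc.state_dict().items()})
    _write(Path(path), arrays,
           _gan_header("gan", disc.n_regions, disc.phen_len, disc.n_classes,
                       disc.cfg))


def load_gan(path: str | Path) -> tuple[GeneratorParams, DiscriminatorParams]:
    arrays, header = _read(Path(path))
    cfg = GANConfig(**header["config"])
    rng = np.random.default_rng(0)
    gen = GeneratorParams(header["n_regions"], cfg, header["n_classes"],
                          header["phen_len"], rng)
    disc = DiscriminatorParams(header["n_regions"], header["phen_len"],
                               header["n_classes"], cfg, rng)
    for k, v in arrays.items():
        if k.startswith("gen_"):
            getattr(gen, k[4:]).data = np.array(v, dtype=np.float64)
    disc.load_state_dict({k[5:]: v for k, v in arrays.items()
                          if k.startswith("disc_")})
    return gen, disc


def save_brainnetcnn(disc: DiscriminatorParams, path: str | Path) -> None:
    _write(Path(path), disc.state_dict(),
           _gan_header("brainnetcnn", disc.n_regions, disc.phen_len,
                       disc.n_classes, disc.cfg))


def load_brainnetcnn(path: str | Path) -> DiscriminatorParams:
    arrays, header = _read(Path(path))
    cfg = GANConfig(**header["config"])
    disc = DiscriminatorParams(header["n_regions"], header["phen_len"],
                               header["n_classes"], cfg,
                               np.random.default_rng(0))
    disc.load_state_dict(arrays)
    return disc
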