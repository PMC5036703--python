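"""Persistence of posterior draws (columnar .npz archive + JSON metadata)."""

from __future__ import annotations

import json

import numpy as np

from .sem import PosteriorDraws

__all__ = ["save_draws", "load_draws"]


def save_draws(draws: PosteriorDraws, path) -> None:
    arrays = {f"draw.{k}": v for k, v in draws.draws.items()}
    arrays.update({f"ll.{k}": v for k, v in draws.pointwise_ll.items()})
    arrays["meta.json"] = np.frombuffer(json.dumps(draws.meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_draws(path) -> PosteriorDraws:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta.json"]).decode())
        draws = {k[len("draw."):]: npz[k] for k in npz.files if k.startswith("draw.")}
        ll = {k[len("ll."):]: npz[k] for k in npz.files if k.startswith("ll.")}
    return PosteriorDraws(draws=draws, pointwise_ll=ll, meta=meta)
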