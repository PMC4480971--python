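"""Balanced/random splitting of the cell-line panel.

The panel is first cut into IC50 tertiles; an outer "balanced split" takes
a uniform random 70% of each tertile as training and the remaining 30% as
balance validation, so both parts span sensitive and resistant lines.  The
outer training part is then cut by a plain (unstratified) random 60/40
inner split into random training and random validation.  Overall the panel
lands in three parts: random training (42%), random validation (28%) and
balance validation (30%).  An ensemble enumerates ``n_outer`` outer splits,
each with ``n_inner`` inner splits; any single split is reconstructible
from (master seed, outer index, inner index).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .containers import PipelineError, ResponsePanel
from .panel_sim import BIMODAL, NORMAL_LIKE

LABEL_RANDOM_TRAIN = "random_train"
LABEL_RANDOM_VAL = "random_val"
LABEL_BALANCE_VAL = "balance_val"


@dataclass
class SplitConfig:
    outer_train_fraction: float = 0.70
    inner_train_fraction: float = 0.60
    n_outer: int = 150
    n_inner: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for f in (self.outer_train_fraction, self.inner_train_fraction):
            if not 0 < f < 1:
                raise PipelineError("split fractions must lie in (0, 1)")


@dataclass
class SplitAssignment:
    """One (outer, inner) split: a partition of the panel into three parts."""

    outer_index: int
    inner_index: int
    random_train: list[str]
    random_val: list[str]
    balance_val: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(s, LABEL_RANDOM_TRAIN) for s in self.random_train]
            + [(s, LABEL_RANDOM_VAL) for s in self.random_val]
            + [(s, LABEL_BALANCE_VAL) for s in self.balance_val]
        )
        df = pd.DataFrame(rows, columns=["sample_id", "label"])
        df.insert(0, "inner_index", self.inner_index)
        df.insert(0, "outer_index", self.outer_index)
        return df


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def remove_middle_tertile(resp: ResponsePanel, ic50_mode: str = NORMAL_LIKE) -> ResponsePanel:
    """Drop the middle third of the panel by log2 IC50 rank.

    Applied only to normal-like IC50 distributions, to sharpen the
    sensitive/resistant contrast before training; for a bimodal panel the
    operation is a no-op (the modes already separate the classes).  Keeps
    the floor(n/3) lowest and floor(n/3) highest IC50 lines.
    """
    if ic50_mode == BIMODAL:
        return resp
    n = len(resp.sample_ids)
    if n < 3:
        raise PipelineError("middle-tertile removal needs at least 3 samples")
    k = n // 3
    order = resp.ic50_log2.sort_values(kind="mergesort").index
    keep = order[:k].append(order[-k:])
    return resp.subset([s for s in resp.sample_ids if s in set(keep)])


def _tertiles(resp: ResponsePanel) -> list[list[str]]:
    order = list(resp.ic50_log2.sort_values(kind="mergesort").index)
    n = len(order)
    q, r = divmod(n, 3)
    sizes = [q + (1 if i < r else 0) for i in range(3)]  # remainders to lower groups
    groups, pos = [], 0
    for s in sizes:
        groups.append(order[pos : pos + s])
        pos += s
    return groups


def balanced_split(
    resp: ResponsePanel, cfg: SplitConfig, outer_seed
) -> tuple[list[str], list[str]]:
    """IC50-tertile-stratified 70/30 split into (train, balance validation)."""
    cfg.validate()
    if len(resp.sample_ids) < 9:
        raise PipelineError("balanced split needs at least 9 samples")
    rng = np.random.default_rng(outer_seed)
    train, balance_val = [], []
    for group in _tertiles(resp):
        if len(group) < 2:
            raise PipelineError("a tertile has fewer than 2 samples")
        n_train = _round_half_up(cfg.outer_train_fraction * len(group))
        perm = rng.permutation(len(group))
        train.extend(group[i] for i in perm[:n_train])
        balance_val.extend(group[i] for i in perm[n_train:])
    return sorted(train), sorted(balance_val)


def inner_random_split(
    train_ids: list[str], cfg: SplitConfig, inner_seed
) -> tuple[list[str], list[str]]:
    """Unstratified 60/40 split of the outer training part."""
    cfg.validate()
    rng = np.random.default_rng(inner_seed)
    ids = list(train_ids)
    n_rt = _round_half_up(cfg.inner_train_fraction * len(ids))
    perm = rng.permutation(len(ids))
    random_train = sorted(ids[i] for i in perm[:n_rt])
    random_val = sorted(ids[i] for i in perm[n_rt:])
    return random_train, random_val


def enumerate_splits(resp: ResponsePanel, cfg: SplitConfig) -> Iterator[SplitAssignment]:
    """Stream all n_outer x n_inner split assignments, deterministically.

    The outer split with index ``o`` uses seed ``[seed, o]`` and its inner
    split ``i`` uses ``[seed, o, i]``, so any assignment can be regenerated
    in isolation.
    """
    cfg.validate()
    for o in range(cfg.n_outer):
        train, balance_val = balanced_split(resp, cfg, [cfg.seed, o])
        for i in range(cfg.n_inner):
            random_train, random_val = inner_random_split(train, cfg, [cfg.seed, o, i])
            yield SplitAssignment(o, i, random_train, random_val, balance_val)
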