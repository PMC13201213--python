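"""Shared fixtures: toy references and simulated libraries, generated at test
time (no stored data files)."""

from __future__ import annotations

import numpy as np
import pytest

from pirnakit.align import Alignment
from pirnakit.refmodel import revcomp
from pirnakit.simulate import (
    SimConfig,
    build_toy_reference,
    simulate_small_rna_population,
)


@pytest.fixture(scope="session")
def bundle():
    """Default toy reference used across the suite."""
    return build_toy_reference(seed=1)


@pytest.fixture(scope="session")
def small_population(bundle):
    """A modest default-parameter library with ground truth."""
    config = SimConfig(seed=11, n_reads=4000)
    return config, simulate_small_rna_population(bundle, config)


def brute_force_map(read_seq: str, targets: dict[str, str], max_mm: int):
    """Independent oracle: full scan over every offset of both strands of
    every target, counting mismatches position by position (N matches
    nothing, including N)."""
    hits: list[tuple[str, int, str, int]] = []
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        for name, target in targets.items():
            for start in range(len(target) - len(seq) + 1):
                mm = 0
                for a, b in zip(seq, target[start : start + len(seq)]):
                    if a != b or a == "N" or b == "N":
                        mm += 1
                        if mm > max_mm:
                            break
                else:
                    hits.append((name, start, strand, mm))
    return hits


def best_strata(hits):
    if not hits:
        return set()
    best = min(h[3] for h in hits)
    return {h for h in hits if h[3] == best}


def alignment_key(aln: Alignment) -> tuple[str, int, str, int]:
    return (aln.target_id, aln.start, aln.strand, aln.mismatches)


def random_reads(rng: np.random.Generator, targets: dict[str, str], n: int):
    """Half planted (substrings with 0-3 mutations, either strand), half
    random sequences; id -> sequence."""
    bases = np.array(list("ACGT"))
    names = list(targets)
    out: dict[str, str] = {}
    for i in range(n):
        L = int(rng.integers(18, 41))
        if i % 2 == 0:
            t = targets[names[int(rng.integers(0, len(names)))]]
            start = int(rng.integers(0, len(t) - L + 1))
            seq = list(t[start : start + L])
            for _ in range(int(rng.integers(0, 4))):
                pos = int(rng.integers(0, L))
                seq[pos] = str(bases[int(rng.integers(0, 4))])
            seq = "".join(seq)
            if rng.random() < 0.5:
                seq = revcomp(seq)
        else:
            seq = "".join(bases[rng.integers(0, 4, size=L)])
        out[f"r{i}"] = seq
    return out
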