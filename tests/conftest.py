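"""Shared fixtures: a small simulation for unit tests and the full-scale
validation fixture (built once per session) for the acceptance checks."""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd
import pytest

import smartmap as sm
from smartmap.coverage import average_depth_over_loci, umap_like_score
from smartmap.metrics import locus_errors, random_select
from smartmap.samprep import bin_by_multiplicity

BASE_SEED = 1


def _dense(track: sm.GenomeWeightTrack) -> Dict[str, np.ndarray]:
    return {c: track.to_dense(c) for c in track.chrom_sizes}


@pytest.fixture(scope="session")
def small_sim() -> sm.SimulatedDataset:
    """A ~60 kb dataset with one exact and one diverged repeat family."""
    cfg = sm.SimulationConfig(
        seed=BASE_SEED,
        genome_length=60_000,
        repeat_families=(
            sm.RepeatFamily(unit_length=400, copies=5, divergence=0.0),
            sm.RepeatFamily(unit_length=600, copies=4, divergence=0.005),
        ),
        n_target_loci=120,
        target_coverage=10.0,
    )
    return sm.simulate(cfg)


@pytest.fixture(scope="session")
def full_sim() -> sm.SimulatedDataset:
    """The full validation fixture: 1 Mb genome, ~42k fragments."""
    return sm.simulate(sm.SimulationConfig(seed=BASE_SEED))


@pytest.fixture(scope="session")
def full_runs(full_sim: sm.SimulatedDataset) -> Dict:
    """All analysis runs of the full fixture, shared by the acceptance tests.

    Returns per-iteration MAEs for rate 1 and rate 0.25, baseline MAEs
    (uniread, random selection), per-iteration conservation diagnostics, and
    the depth tables needed for the mappability analysis.
    """
    ds = full_sim
    bins = bin_by_multiplicity(ds.alignments, k_cap=ds.config.k_cap)
    records = bins.records()
    loci = ds.gold.true_origin_loci
    gold_dense = ds.gold.coverage

    out: Dict = {"bins": bins, "loci": loci, "gold_dense": gold_dense}

    def run_with_snapshots(rate: float) -> Dict:
        maes: Dict[int, float] = {}
        conservation: Dict[int, float] = {}
        track_by_iter: Dict[int, Dict[str, np.ndarray]] = {}

        def snap(it, track, groups):
            maes[it] = locus_errors(gold_dense, _dense(track), loci).mae
            conservation[it] = max(abs(float(g.weights.sum()) - 1.0) for g in groups)
            if it in (0, 1):
                track_by_iter[it] = _dense(track)

        cfg = sm.ReweightConfig(iterations=8, rate=rate, scored=True, read_length=50)
        res = sm.run_smartmap(
            sm.build_read_groups(records), ds.chrom_sizes, cfg, after_iteration=snap
        )
        return {"maes": maes, "conservation": conservation,
                "tracks": track_by_iter, "result": res}

    out["r1"] = run_with_snapshots(1.0)
    out["r025"] = run_with_snapshots(0.25)

    res_uni = sm.run_smartmap(
        sm.build_read_groups(bins.uniread_records()),
        ds.chrom_sizes,
        sm.ReweightConfig(iterations=0),
    )
    out["uniread_dense"] = _dense(res_uni.track)
    out["uniread_mae"] = locus_errors(gold_dense, out["uniread_dense"], loci).mae

    res_rand = sm.run_smartmap(
        sm.build_read_groups(random_select(records, seed=BASE_SEED)),
        ds.chrom_sizes,
        sm.ReweightConfig(iterations=0),
    )
    out["random_mae"] = locus_errors(gold_dense, _dense(res_rand.track), loci).mae

    scores = umap_like_score(ds.genome_str(), k=50)
    out["locus_mappability"] = average_depth_over_loci(scores, loci)["mean"].to_numpy()
    out["gold_locus_depth"] = average_depth_over_loci(gold_dense, loci)["mean"].to_numpy()
    out["smartmap_locus_depth"] = average_depth_over_loci(
        out["r1"]["tracks"][1], loci
    )["mean"].to_numpy()
    out["uniread_locus_depth"] = average_depth_over_loci(
        out["uniread_dense"], loci
    )["mean"].to_numpy()
    return out


@pytest.fixture()
def toy_sam(tmp_path) -> str:
    """A small hand-written SAM exercising the flag whitelist and tags."""
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        "@SQ\tSN:c1\tLN:10000",
        "@SQ\tSN:c2\tLN:5000",
        # r1: proper pair, one alignment; both mates present (147 dropped)
        "r1\t99\tc1\t101\t42\t50M\t=\t226\t175\t" + "A" * 50 + "\t" + "I" * 50 + "\tAS:i:-12\tYS:i:-6",
        "r1\t147\tc1\t226\t42\t50M\t=\t101\t-175\t" + "A" * 50 + "\t" + "I" * 50 + "\tAS:i:-6\tYS:i:-12",
        # r2: two alignments (primary 163 + secondary 355)
        "r2\t163\tc1\t501\t30\t50M\t=\t611\t160\t" + "C" * 50 + "\t" + "I" * 50 + "\tAS:i:0\tYS:i:0",
        "r2\t355\tc2\t301\t30\t50M\t=\t411\t160\t" + "C" * 50 + "\t" + "I" * 50 + "\tAS:i:-18\tYS:i:0",
        # r3: secondary 419 retained; 83/77 never retained
        "r3\t419\tc2\t901\t30\t50M\t=\t1001\t150\t" + "G" * 50 + "\t" + "I" * 50 + "\tAS:i:-6\tYS:i:-6",
        "r4\t83\tc1\t701\t42\t50M\t=\t601\t-150\t" + "T" * 50 + "\t" + "I" * 50 + "\tAS:i:0\tYS:i:0",
        "r5\t77\t*\t0\t0\t*\t*\t0\t0\t" + "T" * 50 + "\t" + "I" * 50,
    ]
    path = tmp_path / "toy.sam"
    path.write_text("\n".join(lines) + "\n")
    return str(path)
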