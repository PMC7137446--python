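import numpy as np
import pandas as pd
import pytest

from dmcpg.simulate import SimConfig, generate_dataset, generate_manifest


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_chromosomes=2, probes_per_chromosome=2000, seed=3)


@pytest.fixture(scope="session")
def small_study(small_config):
    manifest = generate_manifest(small_config)
    matrix, sheet, truth = generate_dataset(small_config, manifest)
    return manifest, matrix, sheet, truth


def make_probe_table(positions, p_values, directions, chrom="chr1",
                     genes=None):
    """Hand-built (diff, manifest) pair for cluster-algorithm tests."""
    n = len(positions)
    ids = [f"p{i}" for i in range(n)]
    manifest = pd.DataFrame({
        "probe_id": ids,
        "chrom": chrom,
        "pos": list(positions),
        "island_relation": "open_sea",
        "gene_symbol": genes if genes is not None else [f"g{i}" for i in range(n)],
        "tss_distance": 0,
        "flag_snp": False,
        "flag_crossreactive": False,
    })
    diff = pd.DataFrame({
        "p_value": list(p_values),
        "delta_beta": [0.1 if d == "hyper" else -0.1 for d in directions],
        "direction": list(directions),
    }, index=pd.Index(ids, name="probe_id"))
    return diff, manifest


def brute_force_clusters(diff, manifest, p_select=1e-4, p_member=1e-2,
                         window=1500):
    """O(n^2) all-pairs window scan + transitive closure over seeds.

    Independent reference for the cluster finder: for every seed collect
    all same-chromosome, same-direction DM probes within the closed
    window; merge seeds by repeatedly unioning any two with intersecting
    member sets until a fixed point; drop singleton groups. Returns a set
    of (chrom, direction, frozenset(member ids)) triples.
    """
    ann = manifest.set_index("probe_id")
    tab = diff.join(ann[["chrom", "pos"]], how="inner")
    groups = []
    for _, row in tab[tab["p_value"] <= p_select].iterrows():
        members = set()
        for pid, other in tab.iterrows():
            if (other["chrom"] == row["chrom"]
                    and other["direction"] == row["direction"]
                    and other["p_value"] <= p_member
                    and abs(other["pos"] - row["pos"]) <= window):
                members.add(pid)
        groups.append((row["chrom"], row["direction"], members))
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                ci, di, mi = groups[i]
                cj, dj, mj = groups[j]
                if ci == cj and di == dj and mi & mj:
                    groups[i] = (ci, di, mi | mj)
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return {(c, d, frozenset(m)) for c, d, m in groups if len(m) >= 2}


def clusters_as_set(clusters):
    return {(c.chrom, c.direction, c.member_probes) for c in clusters}


def random_instance(rng, n_probes=200, n_chrom=2, spike_rate=0.02):
    """Random probe table with spiked-low p-values for oracle comparison."""
    positions, chroms = [], []
    for c in range(n_chrom):
        pos = np.sort(rng.choice(np.arange(1, n_probes * 400), size=n_probes // n_chrom,
                                 replace=False))
        positions.extend(pos.tolist())
        chroms.extend([f"chr{c + 1}"] * len(pos))
    n = len(positions)
    p = rng.uniform(0, 1, n)
    spikes = rng.random(n) < spike_rate
    p[spikes] = rng.uniform(0, 2e-4, spikes.sum())
    medium = rng.random(n) < 0.1
    p[medium & ~spikes] = rng.uniform(0, 2e-2, (medium & ~spikes).sum())
    direction = np.where(rng.random(n) < 0.5, "hyper", "hypo")
    ids = [f"p{i}" for i in range(n)]
    manifest = pd.DataFrame({
        "probe_id": ids, "chrom": chroms, "pos": positions,
        "island_relation": "open_sea", "gene_symbol": "",
        "tss_distance": 0, "flag_snp": False, "flag_crossreactive": False,
    })
    diff = pd.DataFrame({
        "p_value": p,
        "delta_beta": np.where(direction == "hyper", 0.1, -0.1),
        "direction": direction,
    }, index=pd.Index(ids, name="probe_id"))
    return diff, manifest
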