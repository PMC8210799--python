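"""Config-driven orchestration of the full analysis chain.

Stage order mirrors the study design: data (read or simulate) ->
mtDNA statistics -> nuclear statistics -> rarefaction -> ordination ->
marine distances -> isolation by distance -> migration network ->
habitat model.  Any subset of stages can be run; each stage writes tidy
CSV outputs and the run ends with a machine-readable manifest recording
seeds, stage wall times and output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io, habitat_model, migration_flow, multivariate
from . import popgen_mtdna as pm
from . import popgen_nuclear as pn
from . import resampling, seascape_ibd, synth
from ._util import rng_from

log = logging.getLogger("seascape.pipeline")

ALL_STAGES = (
    "data", "mtdna", "nuclear", "rarefaction", "ordination",
    "marine", "ibd", "migration", "habitat",
)

DEFAULT_ENVELOPE = habitat_model.EnvelopeParams({
    # documented placeholder envelope for a cold-temperate coastal
    # odontocete: depth m, SST degC, ice fraction
    "depth": (-650.0, -200.0, -10.0, 0.0),
    "sst": (-2.0, 2.0, 14.0, 20.0),
    "ice": (0.0, 0.0, 0.4, 0.8),
})


def run_pipeline(config: dict, out_dir, stages=None) -> dict:
    """Run the pipeline and return the manifest dictionary.

    ``config`` keys (all optional except ``seed``): ``seed``;
    ``synth`` (SimulationParams overrides, used when no input paths are
    given); ``genotypes``/``alignment``/``metadata`` input paths;
    ``min_loci``; ``g_copies``; ``rarefy_n`` (microsat) and
    ``rarefy_n_mt``; ``depth_window``; ``n_perm``; ``n_boot``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages or ALL_STAGES)
    seed = int(config.get("seed", 0))
    rng = rng_from(seed)
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "seed": seed,
        "stages": [],
    }
    state: dict = {}

    def record(name, t0, outputs, **counts):
        manifest["stages"].append(dict(
            stage=name, seconds=round(time.time() - t0, 2),
            outputs=[str(o) for o in outputs], **counts,
        ))

    # ----- data ---------------------------------------------------------
    if "data" in stages:
        t0 = time.time()
        outputs = []
        if "genotypes" in config:
            state["genotypes"] = data_io.read_genotypes(
                config["genotypes"], min_loci=int(config.get("min_loci", 6))
            )
            state["metadata"] = data_io.read_metadata(config["metadata"])
            if "alignment" in config:
                state["alignment"] = data_io.read_alignment(config["alignment"])
                state["mt_metadata"] = state["metadata"]
        else:
            overrides = dict(config.get("synth", {}))
            overrides.setdefault("seed", seed)
            sim = synth.simulate_metapopulation(
                synth.SimulationParams(**overrides)
            )
            state.update(
                genotypes=sim.genotypes, metadata=sim.metadata,
                alignment=sim.alignment, mt_metadata=sim.mt_metadata,
                truth=sim.truth,
            )
            gp = out / "genotypes.genepop"
            data_io.write_genotypes_genepop(
                sim.genotypes, gp,
                pops=sim.metadata.group_labels(
                    sim.genotypes.individual_ids, "subgroup"),
            )
            fa = out / "alignment.fasta"
            data_io.write_alignment(sim.alignment, fa)
            mc = out / "metadata.csv"
            data_io.write_metadata(sim.metadata, mc)
            outputs += [gp, fa, mc]
        record("data", t0, outputs,
               n_individuals=state["genotypes"].n_individuals,
               n_sequences=state["alignment"].n_sequences
               if "alignment" in state else 0)

    meta = state.get("metadata")
    level = config.get("group_level", "subgroup")

    # ----- mtDNA statistics --------------------------------------------
    if "mtdna" in stages and "alignment" in state:
        t0 = time.time()
        a = state["alignment"]
        labs = state["mt_metadata"].group_labels(a.sequence_ids, level)
        rows = []
        for lab in pd.unique(labs):
            sub = a.subset(np.flatnonzero(labs == lab).tolist())
            div = pm.seq_diversity(sub)
            nt = pm.neutrality_tests(sub)
            rows.append(dict(group=lab, n=sub.n_sequences, **{
                k: div[k] for k in ("Hd", "pi", "thetaW", "S")},
                TajimaD=nt["TajimaD"], FuLiDstar=nt["FuLiDstar"]))
        div_path = out / "mtdna_diversity.csv"
        pd.DataFrame(rows).to_csv(div_path, index=False)
        phist = pm.phi_st_matrix(a, labs, model="TN93")
        ph_path = out / "mtdna_phist.csv"
        data_io.write_distance_csv(phist, ph_path)
        state["phist"] = phist
        record("mtdna", t0, [div_path, ph_path], n_groups=len(rows))

    # ----- nuclear statistics ------------------------------------------
    if "nuclear" in stages:
        t0 = time.time()
        g = state["genotypes"]
        labs = meta.group_labels(g.individual_ids, level)
        hw = pn.heterozygosity_fis(g, labs)
        hw_path = out / "nuclear_diversity.csv"
        g_copies = int(config.get("g_copies", 18))
        ar = pn.allelic_richness(g, labs, g_copies=g_copies)
        hw.join(ar).to_csv(hw_path)
        fst, _ = pn.fst_matrix(g, labs, min_size=int(config.get("min_group", 10)))
        fst_path = out / "nuclear_fst.csv"
        data_io.write_distance_csv(fst, fst_path)
        state["fst"] = fst
        state["nuclear_labels"] = labs
        record("nuclear", t0, [hw_path, fst_path], n_groups=len(hw))

    # ----- rarefaction --------------------------------------------------
    if "rarefaction" in stages:
        t0 = time.time()
        g = state["genotypes"]
        labs = meta.group_labels(g.individual_ids, level)
        n_r = int(config.get("rarefy_n", 14))
        reps = int(config.get("rarefy_reps", 1000))

        def he_stat(table, idx):
            vals = pn.per_locus_he(table, idx)
            return float(np.nanmean(vals))

        recs = resampling.rarefy_statistic(
            g, labs, he_stat, n_individuals=n_r, n_reps=reps,
            seed=rng.integers(2**31 - 1), stat_name="He",
        )
        r_path = out / "rarefied_he.csv"
        resampling.rarefied_frame(recs).to_csv(r_path, index=False)
        record("rarefaction", t0, [r_path], n_groups=len(recs))

    # ----- ordination ---------------------------------------------------
    if "ordination" in stages:
        t0 = time.time()
        g = state["genotypes"]
        X, kept, _ = multivariate.allele_matrix(g, missing="mean")
        res = multivariate.pca(X, n_axes=5)
        scores = pd.DataFrame(
            res.scores,
            index=[g.individual_ids[i] for i in kept],
            columns=[f"PC{k+1}" for k in range(res.scores.shape[1])],
        )
        p_path = out / "pca_scores.csv"
        scores.to_csv(p_path)
        record("ordination", t0, [p_path],
               variance_pc1=float(res.eigenvalues[0]))

    # ----- marine distances --------------------------------------------
    if "marine" in stages:
        t0 = time.time()
        gc = meta.group_coords(level)
        if "bathymetry" in config:
            bathy = data_io.read_raster(config["bathymetry"])
        else:
            bathy = synth.corridor_for_transect(
                gc["lat"].to_numpy(), gc["lon"].to_numpy()
            )
        pts = [(idx, row.lat, row.lon) for idx, row in gc.iterrows()]
        dw = tuple(config.get("depth_window", (-650.0, -10.0)))
        marine = seascape_ibd.marine_distance(bathy, pts, depth_window=dw)
        m_path = out / "marine_distances.csv"
        data_io.write_distance_csv(marine, m_path)
        state["marine"] = marine
        record("marine", t0, [m_path], n_points=len(pts))

    # ----- IBD ----------------------------------------------------------
    if "ibd" in stages:
        t0 = time.time()
        n_perm = int(config.get("n_perm", 10_000))
        if "marine" not in state and "marine_distances" in config:
            state["marine"] = data_io.read_distance_csv(
                config["marine_distances"])
        if "fst" not in state and "genetic_distances" in config:
            state["fst"] = data_io.read_distance_csv(
                config["genetic_distances"], bounded=False)
        if "marine" not in state or not ({"fst", "phist"} & state.keys()):
            raise ValueError(
                "stage 'ibd': missing upstream marine or genetic distance "
                "matrices (run the marine/nuclear/mtdna stages or pass "
                "marine_distances/genetic_distances paths)"
            )
        rows = []
        for key, marker in (("fst", "nuclear"), ("phist", "mtDNA")):
            if key not in state:
                continue
            dm = state[key]
            shared = [l for l in dm.labels if l in state["marine"].labels]
            res = seascape_ibd.ibd_analysis(
                dm.align_to(shared), state["marine"].align_to(shared),
                n_perm=n_perm, seed=rng.integers(2**31 - 1),
                marker_class=marker,
            )
            rows.append(res.__dict__)
        i_path = out / "ibd_results.csv"
        pd.DataFrame(rows).to_csv(i_path, index=False)
        state["ibd"] = rows
        record("ibd", t0, [i_path], n_marker_classes=len(rows))

    # ----- migration network -------------------------------------------
    if "migration" in stages:
        t0 = time.time()
        g = state["genotypes"]
        labs = meta.group_labels(g.individual_ids, level)
        net = migration_flow.directional_migration(
            g, labs, min_size=int(config.get("min_group", 10)),
            n_boot=int(config.get("n_boot", 0)),
            seed=rng.integers(2**31 - 1),
        )
        _, thr = migration_flow.percolation_network(net)
        edges = []
        k = len(net.labels)
        for i in range(k):
            for j in range(k):
                if i != j:
                    edges.append(dict(
                        source=net.labels[i], dest=net.labels[j],
                        m=net.m[i, j], m_raw=net.m_raw[i, j]))
        e_path = out / "migration_edges.csv"
        pd.DataFrame(edges).to_csv(e_path, index=False)
        record("migration", t0, [e_path],
               percolation_threshold=None if np.isnan(thr) else thr)

    # ----- habitat ------------------------------------------------------
    if "habitat" in stages:
        t0 = time.time()
        layers_now = synth.synth_env_layers()
        layers_lgm = synth.synth_env_layers(sst_shift=-4.0)
        env = config.get("envelope", DEFAULT_ENVELOPE)
        maps = {}
        rows = []
        for period, layers in (("present", layers_now), ("LGM", layers_lgm)):
            smap = habitat_model.predict_suitability(layers, env)
            maps[period] = smap
            area = habitat_model.habitat_area(smap, threshold=0.3)
            rows.append(dict(period=period, core_area_km2=area))
        shift = habitat_model.latitude_shift(maps["present"], maps["LGM"])
        h_path = out / "habitat_summary.csv"
        pd.DataFrame(rows).to_csv(h_path, index=False)
        record("habitat", t0, [h_path],
               lat_shift=shift.get("shift"), p=shift.get("p"))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
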