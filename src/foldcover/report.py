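"""Pipeline orchestration, coverage visualizations and report bundles.

`run_pipeline` wires the whole evaluation together from one YAML config:
load and quality-filter the reference set, length-match each sample set,
embed and tokenize everything, compute the Fréchet distance (optionally
stratified by designability and with subsample-convergence diagnostics) and
the length-binned token KL divergences, optionally count motifs, and emit
machine-readable TSV/JSON artifacts plus plots. Every artifact is stamped
with the config hash and seed; reruns with identical config and seed
reproduce all numeric outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import designability as desy
from . import embed as embed_mod
from . import fpd as fpd_mod
from . import motifsearch as motif_mod
from . import secstruct as ss_mod
from . import structio
from . import synth
from . import tokens as tokens_mod

logger = logging.getLogger("foldcover")

DEFAULT_GRID_N = 16


@dataclass
class RasterGrid:
    """Representative-per-cell selection over a 2-D projection: the
    bounding box of the coordinates is split into grid_n equal intervals per
    axis and one uniformly random id is kept per occupied cell."""

    grid_n: int
    cells: dict[tuple[int, int], str]
    bounds: tuple[tuple[float, float], tuple[float, float]]


def raster_select(
    coords: np.ndarray, ids: list[str], grid_n: int = DEFAULT_GRID_N, seed: int = 0
) -> RasterGrid:
    """Pick one random representative per occupied raster cell.

    Cell edges split each axis range into ``grid_n`` equal intervals (the
    maximum edge is inclusive); empty cells are absent from the result.
    Deterministic given ``seed``.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 1:
        raise ValueError("coords must be (n, 2) with n >= 1")
    if len(ids) != coords.shape[0]:
        raise ValueError("ids must match coords")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    cell_of = np.minimum((grid_n * (coords - lo) / span).astype(int), grid_n - 1)
    buckets: dict[tuple[int, int], list[str]] = {}
    for (cx, cy), sid in zip(cell_of, ids):
        buckets.setdefault((int(cy), int(cx)), []).append(sid)
    rng = np.random.default_rng(seed)
    cells = {key: str(rng.choice(buckets[key])) for key in sorted(buckets)}
    return RasterGrid(
        grid_n=grid_n,
        cells=cells,
        bounds=((float(lo[0]), float(hi[0])), (float(lo[1]), float(hi[1]))),
    )


def raster_to_frame(grid: RasterGrid) -> pd.DataFrame:
    rows = [
        {"row": r, "col": c, "id": sid} for (r, c), sid in sorted(grid.cells.items())
    ]
    return pd.DataFrame(rows, columns=["row", "col", "id"])


# ---------------------------------------------------------------------------
# Config handling


_DEFAULTS = {
    "seed": 0,
    "filter": {
        "enabled": True,
        "max_resolution": 3.0,
        "max_rfree": 0.25,
        "exclude_nmr": True,
    },
    "length_match": {"enabled": True, "tolerance": 0},
    "metrics": {
        "fpd": True,
        "kl": True,
        "subsample": [],
        "subsample_reps": 10,
        "alphabet_size": 20,
        "pseudocount": 1.0,
    },
    "raster_grid": DEFAULT_GRID_N,
    "plots": True,
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val, f"{path}{key}.")
        else:
            out[key] = val
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
        base = Path(path_or_dict).parent
    else:
        user = dict(path_or_dict)
        base = Path(".")
    cfg = _merge(_DEFAULTS, user)
    for section in ("reference", "samples", "output_dir"):
        if section not in cfg:
            raise ConfigError(f"config missing required field: {section}")
    cfg["_base"] = str(base)
    return cfg


def config_hash(cfg: dict) -> str:
    clean = {k: v for k, v in cfg.items() if not k.startswith("_")}
    return hashlib.sha256(
        json.dumps(clean, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _resolve(base: str, p: str) -> Path:
    path = Path(p)
    return path if path.is_absolute() else Path(base) / path


def _load_set(base: str, section: dict) -> list[tuple]:
    if "manifest" in section:
        return structio.read_manifest(_resolve(base, section["manifest"]))
    if "pdb_dir" in section:
        d = _resolve(base, section["pdb_dir"])
        files = sorted(d.glob("*.pdb"))
        if not files:
            raise ConfigError(f"no PDB files in {d}")
        return [structio.read_backbone(f) for f in files]
    raise ConfigError("a structure set needs 'pdb_dir' or 'manifest'")


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(config) -> dict:
    """Execute the full coverage evaluation described by a config mapping or
    YAML path; returns the report dict (also written to
    ``<output_dir>/report.json``)."""
    cfg = load_config(config)
    base = cfg["_base"]
    seed = int(cfg["seed"])
    out_dir = _resolve(base, cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    t0 = time.time()
    report: dict = {"config_hash": chash, "seed": seed, "sets": {}}

    mcfg = cfg["metrics"]
    ref_structs: list | None = None
    if "embeddings" in cfg["reference"]:
        # precomputed embeddings (external encoder); no structures available,
        # so token/secondary-structure analyses are skipped for this run
        ref_emb = embed_mod.read_embeddings(_resolve(base, cfg["reference"]["embeddings"]))
        ref_emb.group = ["reference"] * ref_emb.n
        if mcfg["kl"]:
            logger.info("stage=reference kl disabled (embedding-backed reference)")
            mcfg = dict(mcfg, kl=False)
    else:
        ref_records = _load_set(base, cfg["reference"])
        logger.info(
            "stage=load_reference n=%d t=%.2fs", len(ref_records), time.time() - t0
        )
        fcfg = cfg["filter"]
        if fcfg["enabled"]:
            ref_records, reasons = structio.filter_reference_set(
                ref_records,
                max_resolution=fcfg["max_resolution"],
                max_rfree=fcfg["max_rfree"],
                exclude_nmr=fcfg["exclude_nmr"],
            )
            report["reference_filter"] = dict(reasons)
            if not ref_records:
                raise ConfigError("reference set empty after filtering")
        ref_structs = [bb for bb, _ in ref_records]
        ref_emb = embed_mod.embed_structures(ref_structs, group="reference")
    report["n_reference"] = ref_emb.n

    codebook = None
    if mcfg["kl"]:
        desc = np.vstack(
            [embed_mod.residue_descriptors(s)[1] for s in ref_structs]
        )
        a_size = int(mcfg["alphabet_size"])
        codebook = tokens_mod.fit_codebook(desc, alphabet_size=a_size, seed=seed)
        ref_seqs = [
            (tokens_mod.tokenize(s, codebook), s.length) for s in ref_structs
        ]
        ref_table = tokens_mod.count_frequencies(
            ref_seqs, a_size, pseudocount=float(mcfg["pseudocount"])
        )
        tokens_mod.save_codebook(codebook, out_dir / "codebook.txt")

    embed_mod.write_embeddings(ref_emb, out_dir / "embeddings_reference.tsv")
    all_emb = [ref_emb]

    for samp_cfg in cfg["samples"]:
        name = samp_cfg.get("name", "sample")
        if "embeddings" in samp_cfg:
            semb = embed_mod.read_embeddings(_resolve(base, samp_cfg["embeddings"]))
            semb.group = [name] * semb.n
            samp_structs = None
            set_report: dict = {"n_loaded": semb.n, "n_used": semb.n}
        else:
            samp_records = _load_set(base, samp_cfg)
            samp_structs = [bb for bb, _ in samp_records]
            set_report = {"n_loaded": len(samp_structs)}
            lcfg = cfg["length_match"]
            if lcfg["enabled"] and ref_structs is not None:
                idx, shortfall = structio.match_length_distribution(
                    [s.length for s in samp_structs],
                    [s.length for s in ref_structs],
                    seed=seed,
                    tolerance=int(lcfg["tolerance"]),
                )
                samp_structs = [samp_structs[i] for i in idx]
                set_report["length_shortfall"] = {
                    str(k): v for k, v in shortfall.items()
                }
            set_report["n_used"] = len(samp_structs)
            if not samp_structs:
                raise ConfigError(f"sample set {name!r} empty after length matching")
            semb = embed_mod.embed_structures(samp_structs, group=name)
        if "designability_table" in samp_cfg:
            recs = desy.records_from_table(
                _resolve(base, samp_cfg["designability_table"])
            )
            flag_of = {r.structure_id: r.designable for r in recs}
            semb.designable = np.array(
                [flag_of.get(sid, False) for sid in semb.ids]
            )
        embed_mod.write_embeddings(semb, out_dir / f"embeddings_{name}.tsv")
        all_emb.append(semb)

        if mcfg["fpd"]:
            if semb.designable is not None:
                rep = fpd_mod.fpd_stratified(ref_emb, semb)
                set_report["fpd"] = rep.fpd
                set_report["fpd_d"] = rep.fpd_d
                set_report["fpd_nd"] = rep.fpd_nd
                set_report["fpd_gap"] = rep.gap
            else:
                set_report["fpd"] = fpd_mod.fpd(
                    fpd_mod.summarize(ref_emb), fpd_mod.summarize(semb)
                )
            sizes = [s for s in mcfg["subsample"] if s <= semb.n]
            if sizes:
                curve = fpd_mod.subsample_convergence(
                    ref_emb, semb, sizes, reps=int(mcfg["subsample_reps"]), seed=seed
                )
                curve.to_csv(out_dir / f"subsample_{name}.tsv", sep="\t", index=False)
                set_report["subsample"] = curve.to_dict(orient="records")
        if mcfg["kl"] and samp_structs is not None:
            samp_seqs = [
                (tokens_mod.tokenize(s, codebook), s.length) for s in samp_structs
            ]
            samp_table = tokens_mod.count_frequencies(
                samp_seqs, int(mcfg["alphabet_size"]),
                pseudocount=float(mcfg["pseudocount"]),
            )
            kl = tokens_mod.kl_tables(ref_table, samp_table)
            set_report["kl_unigram"] = kl["unigram"]
            set_report["kl_bigram"] = kl["bigram"]
            set_report["kl_unigram_reverse"] = kl["unigram_reverse"]
            pd.DataFrame(kl["per_bin"]).to_csv(
                out_dir / f"kl_bins_{name}.tsv", sep="\t", index=False
            )
        if samp_structs is not None:
            contents = [ss_mod.ss_content(ss_mod.assign_ss(s)) for s in samp_structs]
            set_report["ss_content"] = {
                "alpha": float(np.mean([c.alpha for c in contents])),
                "beta": float(np.mean([c.beta for c in contents])),
                "loop": float(np.mean([c.loop for c in contents])),
            }
        report["sets"][name] = set_report
        logger.info("stage=sample_set name=%s t=%.2fs", name, time.time() - t0)

    # Pooled projection, raster and plots
    # group-qualified ids keep pooled rows unique (a set may appear twice,
    # e.g. in a self-comparison run)
    pooled = embed_mod.concat_embeddings(
        [
            embed_mod.EmbeddingMatrix(
                m.values,
                [f"{g}:{sid}" for g, sid in zip(m.group, m.ids)],
                m.group,
                length=m.length,
            )
            for m in all_emb
        ]
    )
    coords, evr = embed_mod.pca_project(pooled, k=2)
    embed_mod.write_projection(pooled, coords, out_dir / "projection.tsv")
    report["pca_explained_variance"] = [float(v) for v in evr]
    grid = raster_select(coords, pooled.ids, grid_n=int(cfg["raster_grid"]), seed=seed)
    raster_to_frame(grid).to_csv(out_dir / "raster.tsv", sep="\t", index=False)
    report["raster_occupied_cells"] = len(grid.cells)

    if cfg.get("motifs") and ref_structs is not None:
        motif_dir = _resolve(base, cfg["motifs"]["dir"])
        overrides = {}
        if "sigma_overrides" in cfg["motifs"]:
            overrides = motif_mod.read_sigma_overrides(
                _resolve(base, cfg["motifs"]["sigma_overrides"])
            )
        motifs = []
        for f in sorted(motif_dir.glob("*.pdb")):
            m = motif_mod.read_motif(f)
            if m.name in overrides:
                m.sigma_max = overrides[m.name]
            motifs.append(m)
        sets = {"reference": ref_structs}
        counts = motif_mod.count_matches(motifs, sets)
        counts.to_csv(out_dir / "motif_counts.tsv", sep="\t", index=False)
        report["motif_counts"] = counts.to_dict(orient="records")

    if cfg["plots"]:
        make_plots(out_dir)

    report["wall_time_s"] = round(time.time() - t0, 3)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(
            {k: v for k, v in report.items() if k != "wall_time_s"},
            fh,
            sort_keys=True,
            indent=2,
            default=_json_default,
        )
        fh.write("\n")
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def make_plots(out_dir: Path) -> list[Path]:
    """Render plots from the emitted TSV artifacts (never recomputing the
    metrics): PCA scatter by group, per-bin KL bars, subsample curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    plot_dir = out_dir / "plots"
    plot_dir.mkdir(exist_ok=True)
    written = []

    proj = out_dir / "projection.tsv"
    if proj.exists():
        df = pd.read_csv(proj, sep="\t")
        fig, ax = plt.subplots(figsize=(6, 5))
        for grp, sub in df.groupby("group"):
            ax.scatter(sub["pc1"], sub["pc2"], s=8, alpha=0.6, label=grp)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend()
        fig.savefig(plot_dir / "pca_scatter.png", dpi=120)
        plt.close(fig)
        written.append(plot_dir / "pca_scatter.png")

    for klf in sorted(out_dir.glob("kl_bins_*.tsv")):
        df = pd.read_csv(klf, sep="\t")
        if df.empty:
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(df["lo"], df["unigram_kl"], width=40, label="unigram")
        ax.set_xlabel("length bin lower edge")
        ax.set_ylabel("KL (nats)")
        ax.set_title(klf.stem)
        ax.legend()
        fig.savefig(plot_dir / f"{klf.stem}.png", dpi=120)
        plt.close(fig)
        written.append(plot_dir / f"{klf.stem}.png")

    for sf in sorted(out_dir.glob("subsample_*.tsv")):
        df = pd.read_csv(sf, sep="\t")
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.errorbar(df["size"], df["mean_fpd"], yerr=df["std_fpd"], marker="o")
        ax.set_xscale("log")
        ax.set_xlabel("subsample size")
        ax.set_ylabel("FPD")
        ax.set_title(sf.stem)
        fig.savefig(plot_dir / f"{sf.stem}.png", dpi=120)
        plt.close(fig)
        written.append(plot_dir / f"{sf.stem}.png")
    return written


# ---------------------------------------------------------------------------
# Fixture bundles (synthetic end-to-end inputs)


def write_fixture_bundle(
    out_dir,
    seed: int = 0,
    n_reference: int = 40,
    n_sample: int = 40,
    self_comparison: bool = False,
) -> Path:
    """Write a complete synthetic input bundle: reference and sample PDB
    directories, manifests, and a ready-to-run pipeline config. With
    ``self_comparison`` the sample set IS the reference set (the pipeline
    should then report near-zero FPD and KL).

    Returns the config path.
    """
    out_dir = Path(out_dir)
    ref_dir = out_dir / "reference"
    ref_dir.mkdir(parents=True, exist_ok=True)
    ref = synth.make_structure_set(n_reference, seed=seed, prefix="ref")
    for s in ref:
        structio.write_backbone(s, ref_dir / f"{s.id}.pdb")
    if self_comparison:
        samp_dir = ref_dir
    else:
        samp_dir = out_dir / "samples"
        samp_dir.mkdir(exist_ok=True)
        # a biased sampler: over-represents helices relative to the reference
        samp = synth.make_structure_set(
            n_sample, seed=seed + 1, classes=("helix", "helix", "strand", "mixed"),
            prefix="samp",
        )
        for s in samp:
            structio.write_backbone(s, samp_dir / f"{s.id}.pdb")
    cfg = {
        "seed": seed,
        "output_dir": "out",
        "reference": {"pdb_dir": str(ref_dir.name)},
        "samples": [
            {
                "name": "self" if self_comparison else "model",
                "pdb_dir": str(samp_dir.relative_to(out_dir)),
            }
        ],
        "filter": {"enabled": False},
        "length_match": {"enabled": False},
        "metrics": {"alphabet_size": 6, "subsample": []},
        "raster_grid": 16,
        "plots": False,
    }
    cfg_path = out_dir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg_path
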