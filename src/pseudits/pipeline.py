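"""End-to-end orchestration: clones -> variants -> screen -> scan -> trees
-> concordance, with machine-readable reports and a checksum MANIFEST.

The pipeline is deliberately thin glue over the library modules; every
number in its reports is produced by one of them.  Logs go to stderr,
reports to the output directory, and a fixed config (including seeds)
reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import __version__
from .clone_analysis import (DEFAULT_LENGTH_THRESHOLD, DEFAULT_MAX_INTRA_DIFF,
                             build_catalogue)
from .concordance import (AccessionSummary, ConcordanceError, build_patterns,
                          association_test, classify_evolutionary_category)
from .errors import PipelineError, ScanError
from .phylo import bootstrap_support, k2p_matrix, root_on_outgroup
from .pseudogene_screen import (ScreenThresholds, classify_pseudogene,
                                consensus_profile, profile_copy)
from .recombination_scan import scan_triplet
from .seqio import (CloneSet, annotate_regions, load_reference_its,
                    progressive_msa, read_fasta, write_fasta)

log = logging.getLogger("pseudits")


@dataclass
class PipelineConfig:
    clones_dir: str = "clones"
    cpdna_dir: str = "cpdna"
    reference_its: str | None = None     # FASTA + JSON regions; packaged default
    long_reference: str | None = None    # long-type reference for the 13-mer
    outgroup: str | None = None          # taxon label in the cpDNA FASTA
    length_threshold: int = DEFAULT_LENGTH_THRESHOLD
    max_intra_diff: int = DEFAULT_MAX_INTRA_DIFF
    gc_delta: float = 0.02
    mfe_delta: float = 2.0
    length_tolerance: int = 3
    motif_max_mismatch: int = 1
    bootstrap_n: int = 200
    phylo_seed: int = 0
    scan_permutations: int = 999
    scan_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise PipelineError("config", f"unknown config keys: {sorted(bad)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_clone_sets(clones_dir: Path) -> list[CloneSet]:
    files = sorted(clones_dir.glob("*.fasta"))
    if not files:
        raise PipelineError("variants",
                            f"no clone FASTA files found in {clones_dir}")
    return [CloneSet(accession_name=f.stem,
                     clones=tuple(read_fasta(f, molecule="ITS")))
            for f in files]


def run_pipeline(cfg: PipelineConfig, indir: str | Path,
                 outdir: str | Path, stop_after: str | None = None) -> dict:
    """Execute all stages; returns the report dict written to report.json.

    stop_after ("variants" | "screen" | "scan") truncates the run after
    that stage; the MANIFEST then marks the bundle as partial.
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    report: dict = {"version": __version__,
                    "config": dataclasses.asdict(cfg)}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest[name] = _sha256(path)

    def fail(stage: str, message: str):
        (outdir / "MANIFEST.json").write_text(json.dumps(
            {"complete": False, "failed_stage": stage, "files": manifest},
            indent=1))
        raise PipelineError(stage, message)

    def stop(stage: str) -> dict:
        (outdir / "MANIFEST.json").write_text(json.dumps(
            {"complete": False, "stopped_after": stage, "files": manifest},
            indent=1))
        return report

    # ---- stage 1: variants --------------------------------------------
    log.info("stage variants: clustering clone sets")
    clone_sets = _read_clone_sets(indir / cfg.clones_dir)
    long_ref = None
    if cfg.long_reference:
        # the longest record in the file serves as the long-type reference
        long_ref = max(read_fasta(indir / cfg.long_reference), key=len)
    catalogues = []
    for cs in clone_sets:
        try:
            catalogues.append(build_catalogue(
                cs, max_intra_diff=cfg.max_intra_diff,
                length_threshold=cfg.length_threshold,
                long_reference=long_ref))
        except Exception as exc:  # noqa: BLE001 - stage boundary
            fail("variants", f"accession {cs.accession_name}: {exc}")
    var_rows = []
    consensi = []
    for cat in catalogues:
        for v in cat.variants:
            var_rows.append({
                "accession": cat.accession_name,
                "copy_id": v.consensus.id,
                "rank_label": v.rank_label,
                "length_class": v.length_class,
                "length_bp": v.length_bp,
                "support": v.support,
                "heterozygosity_pct": cat.heterozygosity_pct,
                "thirteenmer_allele": cat.thirteenmer_allele,
            })
            consensi.append(v.consensus)
    variants_df = pd.DataFrame(var_rows)
    emit("variants.tsv",
         lambda p: variants_df.to_csv(p, sep="\t", index=False))
    emit("consensus.fasta", lambda p: write_fasta(consensi, p))
    if stop_after == "variants":
        return stop("variants")

    # ---- stage 2: pseudogene screen -----------------------------------
    log.info("stage screen: profiling %d consensus copies", len(consensi))
    if cfg.reference_its:
        ref = read_fasta(indir / cfg.reference_its)[0]
        meta = json.loads((indir / cfg.reference_its)
                          .with_suffix(".json").read_text())
        from .seqio import ItsRegions
        ref_regions = ItsRegions(its1=tuple(meta["its1"]),
                                 r58s=tuple(meta["r58s"]),
                                 its2=tuple(meta["its2"]))
    else:
        ref, ref_regions = load_reference_its()
    thresholds = ScreenThresholds(
        gc_delta=cfg.gc_delta, mfe_delta=cfg.mfe_delta,
        length_tolerance=cfg.length_tolerance,
        motif_max_mismatch=cfg.motif_max_mismatch)
    profiles: dict[str, object] = {}
    try:
        for cat in catalogues:
            for v in cat.variants:
                regions = annotate_regions(v.consensus, ref, ref_regions)
                profiles[v.consensus.id] = profile_copy(
                    v, regions, motif_max_mismatch=cfg.motif_max_mismatch)
    except Exception as exc:  # noqa: BLE001
        fail("screen", str(exc))
    majors = {cat.accession_name: cat.variants[0] for cat in catalogues}
    class_profiles = {}
    for cls in ("short", "long"):
        ps = [profiles[v.consensus.id] for v in majors.values()
              if v.length_class == cls]
        if ps:
            class_profiles[cls] = consensus_profile(ps)
    calls = {}
    screen_rows = []
    for cat in catalogues:
        major = cat.variants[0]
        for v in cat.variants:
            prof = profiles[v.consensus.id]
            if v is major:
                baseline = class_profiles.get(v.length_class)
                if baseline is None or len(cat.variants) > 1:
                    continue  # majors with a minor are the reference side
            else:
                baseline = profiles[major.consensus.id]
            call = classify_pseudogene(prof, baseline, thresholds)
            calls[v.consensus.id] = (cat.accession_name, v, call)
            screen_rows.append({
                "accession": cat.accession_name,
                "copy_id": call.copy_id,
                **{f"criterion_{k}": v_ for k, v_ in call.criteria.items()},
                **{k: round(v_, 4) for k, v_ in call.deltas.items()},
                "verdict": call.verdict,
            })
    emit("screen.tsv", lambda p: pd.DataFrame(screen_rows)
         .to_csv(p, sep="\t", index=False))
    if stop_after == "screen":
        return stop("screen")

    # ---- stage 3: recombination scan ----------------------------------
    pseudo = {cid: (acc, v) for cid, (acc, v, call) in calls.items()
              if call.verdict == "pseudogene"}
    log.info("stage scan: %d pseudogene candidates", len(pseudo))
    long_majors = [v.consensus for v in majors.values()
                   if v.length_class == "long"]
    long_parent = long_majors[0] if long_majors else None
    scan_rows = []
    for cid in sorted(pseudo):
        acc, v = pseudo[cid]
        parent_a = majors[acc].consensus
        if long_parent is None or parent_a.id == long_parent.id:
            continue
        try:
            res = scan_triplet(v.consensus, parent_a, long_parent,
                               n_permutations=cfg.scan_permutations,
                               seed=cfg.scan_seed)
        except ScanError:
            continue
        scan_rows.append({
            "query_id": res.query_id, "parent_a": res.parents[0],
            "parent_b": res.parents[1], "breakpoint": res.best_breakpoint,
            "chi2_max": round(res.chi2_max, 4), "p_value": res.p_value,
            "informative_sites": res.informative_sites,
        })
    emit("scan.tsv", lambda p: pd.DataFrame(
        scan_rows, columns=["query_id", "parent_a", "parent_b", "breakpoint",
                            "chi2_max", "p_value", "informative_sites"])
        .to_csv(p, sep="\t", index=False))
    if stop_after == "scan":
        return stop("scan")

    # ---- stage 4: trees ------------------------------------------------
    log.info("stage tree: ITS and cpDNA phylogenies")
    try:
        its_aln = progressive_msa(consensi)
        its_tree = bootstrap_support(its_aln, n_reps=cfg.bootstrap_n,
                                     seed=cfg.phylo_seed)
        emit("its_tree.nwk", lambda p: Path(p).write_text(
            its_tree.newick() + "\n"))
        cp_dir = indir / cfg.cpdna_dir
        lf = read_fasta(cp_dir / "trnL-trnF.fasta", molecule="trnL-trnF")
        tl = read_fasta(cp_dir / "trnT-trnL.fasta", molecule="trnT-trnL")
        from .phylo import concat_cpdna
        cp_aln = concat_cpdna(progressive_msa(lf), progressive_msa(tl))
        cp_tree = bootstrap_support(cp_aln, n_reps=cfg.bootstrap_n,
                                    seed=cfg.phylo_seed)
        if cfg.outgroup:
            cp_tree = root_on_outgroup(cp_tree, cfg.outgroup)
        emit("cpdna_tree.nwk", lambda p: Path(p).write_text(
            cp_tree.newick() + "\n"))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("tree", str(exc))

    # ---- stage 5: concordance ------------------------------------------
    log.info("stage concord: connection patterns")
    pseudogroups = _pseudogroup_labels([v.consensus for _, v in
                                        pseudo.values()])
    cp_clades = _cpdna_clades(cp_tree, cfg.outgroup)
    pg_by_acc = {}
    for cid, (acc, v) in sorted(pseudo.items()):
        pg_by_acc[acc] = pseudogroups.get(cid, "none")
    clade_by_acc = {acc: cp_clades.get(acc, "other") for acc in
                    (c.accession_name for c in catalogues)}
    patterns = build_patterns(pg_by_acc, clade_by_acc)
    try:
        p_val, table, rows_lbl, cols_lbl = association_test(
            patterns, n_permutations=cfg.scan_permutations,
            seed=cfg.scan_seed)
        assoc = {"p_value": p_val, "table": table.tolist(),
                 "pseudogroups": rows_lbl, "clades": cols_lbl}
    except ConcordanceError as exc:
        assoc = {"p_value": None, "note": str(exc)}
    categories = []
    for cat in catalogues:
        pseudo_classes = tuple(v.length_class for _, v in
                               (pseudo.get(vv.consensus.id, (None, None))
                                for vv in cat.variants)
                               if v is not None)
        functional = tuple(v.length_class for v in cat.variants
                           if v.consensus.id not in pseudo)
        if not functional:
            continue
        summary = AccessionSummary(
            accession_name=cat.accession_name,
            functional_classes=functional,
            pseudogene_classes=pseudo_classes,
            pseudogroups=tuple(
                pseudogroups[v.consensus.id] for v in cat.variants
                if v.consensus.id in pseudogroups),
            cpdna_clade=clade_by_acc.get(cat.accession_name, "other"))
        categories.append(classify_evolutionary_category(summary))
    concord = {
        "patterns": [dataclasses.asdict(p) for p in patterns],
        "association": assoc,
        "categories": [dataclasses.asdict(c) for c in categories],
    }
    emit("patterns.json",
         lambda p: Path(p).write_text(json.dumps(concord, indent=1)))

    report["n_accessions"] = len(catalogues)
    report["n_variants"] = len(consensi)
    report["n_pseudogenes"] = len(pseudo)
    report["patterns"] = concord["patterns"]
    report["association_p"] = assoc.get("p_value")
    emit("report.json",
         lambda p: Path(p).write_text(json.dumps(report, indent=1)))
    (outdir / "MANIFEST.json").write_text(json.dumps(
        {"complete": True, "files": manifest}, indent=1))
    log.info("pipeline complete: %d accessions, %d pseudogenes",
             len(catalogues), len(pseudo))
    return report


def _pseudogroup_labels(records) -> dict[str, str]:
    """Split pseudogene copies into two groups by K2P average linkage.

    The group containing the lexicographically smallest copy id is
    "pseudogroup 1".  Fewer than two copies: all labelled pseudogroup 1.
    """
    if not records:
        return {}
    if len(records) == 1:
        return {records[0].id: "pseudogroup 1"}
    aln = progressive_msa(records)
    dm = k2p_matrix(aln)
    z = linkage(squareform(dm.d, checks=False), method="average")
    groups = fcluster(z, t=2, criterion="maxclust")
    first = min(range(len(records)), key=lambda i: records[i].id)
    mapping = {groups[first]: "pseudogroup 1"}
    for g in sorted(set(groups)):
        mapping.setdefault(g, "pseudogroup 2")
    return {r.id: mapping[g] for r, g in zip(records, groups)}


def _cpdna_clades(cp_tree, outgroup: str | None) -> dict[str, str]:
    """Clade I / clade II labels from the root split of the cpDNA tree.

    The ingroup side of the root with the lexicographically smallest
    accession is clade I.  Without an outgroup the deepest split is used.
    """
    tree = cp_tree.tree
    split_node = tree.seed_node
    if outgroup is not None:
        # descend past the outgroup: the ingroup root carries the I/II split
        for child in tree.seed_node.child_nodes():
            labels_below = {l.taxon.label for l in child.leaf_iter()}
            if outgroup not in labels_below:
                split_node = child
                break
    sides = []
    for child in split_node.child_nodes():
        leaves = sorted(l.taxon.label for l in child.leaf_iter()
                        if l.taxon.label != outgroup)
        if leaves:
            sides.append(leaves)
    sides = sorted(sides, key=lambda s: s[0])
    labels = {}
    for idx, side in enumerate(sides[:2]):
        name = "clade I" if idx == 0 else "clade II"
        for taxon in side:
            labels[taxon] = name
    for side in sides[2:]:
        for taxon in side:
            labels[taxon] = "other"
    return labels
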