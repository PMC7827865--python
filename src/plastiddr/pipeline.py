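"""End-to-end orchestration: genomes in, report bundle out.

Each stage communicates with the next only through serialized TSV/JSON in
the run directory, so any stage can be re-run in isolation and the bundle
diffs cleanly. Results go to stdout/files; logging goes to stderr.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import content, diversity, editing, structure
from .genbank_io import read_genbank
from .records import PlastomeRecord

log = logging.getLogger("plastiddr")


@dataclass
class RunConfig:
    inputs: list[str]
    out_dir: str
    groups: dict[str, str] = field(default_factory=dict)
    min_repeat: int = structure.DEFAULT_MIN_REPEAT
    max_divergence: float = structure.DEFAULT_MAX_DIVERGENCE
    min_depth: int = editing.DEFAULT_MIN_DEPTH
    min_ratio: float = editing.DEFAULT_MIN_RATIO
    alignments: dict[str, str] = field(default_factory=dict)  # record id -> SAM/BAM
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


def _threshold_header(cfg: RunConfig) -> str:
    return (
        f"# min_repeat={cfg.min_repeat} max_divergence={cfg.max_divergence} "
        f"min_depth={cfg.min_depth} min_ratio={cfg.min_ratio}\n"
        "# indel_unit=one event per maximal contiguous gap run\n"
    )


def run_all(cfg: RunConfig) -> dict:
    """Run every stage over the input genomes; returns the MANIFEST dict.

    Emits structure.json, structure.bed, matrix.tsv, introns.tsv,
    stats.tsv, editing.tsv, diversity.tsv and summary.md under the run
    directory; a stage failure is recorded in MANIFEST.json and partial
    outputs are kept.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_json(out / "run_config.json")
    manifest: dict[str, str] = {}
    t0 = time.time()

    records: list[PlastomeRecord] = []
    for path in cfg.inputs:
        records.extend(read_genbank(path))
    log.info("loaded %d records in %.1fs", len(records), time.time() - t0)

    parts: dict[str, structure.QuadripartitePartition | None] = {}

    def stage(name):
        def wrap(fn):
            t = time.time()
            try:
                fn()
                manifest[name] = "ok"
            except Exception as exc:  # keep partial outputs, note failure
                log.error("stage %s failed: %s", name, exc)
                manifest[name] = f"failed: {exc}"
            log.info("stage %s: %s (%.1fs)", name, manifest[name], time.time() - t)

        return wrap

    @stage("structure")
    def _structure():
        rows = []
        bed_lines = []
        for r in records:
            part = structure.analyse(
                r, min_len=cfg.min_repeat, max_divergence=cfg.max_divergence
            )
            parts[r.id] = part
            if part is None:
                rows.append({"id": r.id, "species": r.species, "orientation": "none"})
                continue
            lengths = part.lengths(r.length)
            rows.append(
                {
                    "id": r.id,
                    "species": r.species,
                    "orientation": part.orientation,
                    "identity": round(part.repeats.identity, 5),
                    "label_basis": part.label_basis,
                    **lengths,
                }
            )
            offset = structure.canonical_rotation_offset(part)
            for label, iv in part.labels.items():
                s = (iv.start - offset) % r.length
                e = s + iv.length(r.length)
                if e <= r.length:
                    bed_lines.append(f"{r.id}\t{s}\t{e}\t{label}")
                else:  # wrapping arc on the canonical rotation
                    bed_lines.append(f"{r.id}\t{s}\t{r.length}\t{label}")
                    bed_lines.append(f"{r.id}\t0\t{e - r.length}\t{label}")
        with open(out / "structure.json", "w") as fh:
            json.dump(rows, fh, indent=1)
        (out / "structure.bed").write_text("\n".join(bed_lines) + "\n")

    @stage("stats")
    def _stats():
        rows = []
        for r in records:
            part = parts.get(r.id)
            if part is None:
                continue
            rows.append(content.stats(r, part).as_row())
        df = pd.DataFrame(rows)
        with open(out / "stats.tsv", "w") as fh:
            fh.write(_threshold_header(cfg))
            df.to_csv(fh, sep="\t", index=False)

    @stage("matrix")
    def _matrix():
        m = content.build_matrix(records)
        m.to_tsv(out / "matrix.tsv")

    @stage("introns")
    def _introns():
        rows = []
        for r in records:
            for ir in content.intron_survey(r):
                rows.append(ir.__dict__)
        pd.DataFrame(rows).to_csv(out / "introns.tsv", sep="\t", index=False)

    @stage("editing")
    def _editing():
        rows = []
        for r in records:
            classifications, summary = editing.survey_codons(r)
            calls = {}
            if r.id in cfg.alignments:
                from .pileup import read_alignments

                counts = read_alignments(cfg.alignments[r.id], r)
                for call in editing.confirm_editing(
                    r, classifications, counts, cfg.min_depth, cfg.min_ratio
                ):
                    calls[(call.gene, call.position_kind)] = call
            for c in classifications:
                call = calls.get((c.gene, c.position_kind))
                rows.append(
                    {
                        "species": r.species,
                        "gene": c.gene,
                        "kind": c.position_kind,
                        "codon": c.codon,
                        "class": c.klass,
                        "c_count": call.c_count if call else "",
                        "t_count": call.t_count if call else "",
                        "edit_ratio": round(call.edit_ratio, 4) if call else "",
                        "confirmed": call.confirmed if call else "",
                    }
                )
        with open(out / "editing.tsv", "w") as fh:
            fh.write(_threshold_header(cfg))
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)

    @stage("diversity")
    def _diversity():
        rows = []
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                a, b = records[i], records[j]
                try:
                    pv = diversity.pairwise_variants(a.seq, b.seq, a.id, b.id)
                    rows.append(
                        {
                            "idA": a.id,
                            "idB": b.id,
                            "snp_count": pv.snp_count,
                            "indel_event_count": pv.indel_event_count,
                            "indel_bp": pv.indel_bp,
                            "aligned_fraction": round(pv.aligned_fraction, 4),
                        }
                    )
                except diversity.NotCollinearError as exc:
                    rows.append(
                        {"idA": a.id, "idB": b.id, "snp_count": "",
                         "indel_event_count": "", "indel_bp": "",
                         "aligned_fraction": "", "note": str(exc)}
                    )
        with open(out / "diversity.tsv", "w") as fh:
            fh.write(_threshold_header(cfg))
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)

    @stage("summary")
    def _summary():
        lines = ["# plastiddr run summary", ""]
        lines.append(f"Inputs: {len(records)} genome(s)")
        with open(out / "structure.json") as fh:
            srows = json.load(fh)
        n_dr = sum(1 for r in srows if r.get("orientation") == "direct")
        n_ir = sum(1 for r in srows if r.get("orientation") == "inverted")
        lines.append(f"Repeat orientation: {n_dr} direct, {n_ir} inverted")
        lines.append("")
        lines.append("| id | species | orientation | LSC | SSC | repeat |")
        lines.append("|---|---|---|---|---|---|")
        for r in srows:
            lines.append(
                f"| {r['id']} | {r['species']} | {r.get('orientation','')} "
                f"| {r.get('LSC','')} | {r.get('SSC','')} | {r.get('RepA','')} |"
            )
        (out / "summary.md").write_text("\n".join(lines) + "\n")

    manifest["elapsed_s"] = f"{time.time() - t0:.1f}"
    with open(out / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def render_summary(bundle_dir: str | Path, fmt: str = "png") -> list[Path]:
    """Render figures from an existing bundle; purely presentational.

    Produces a stacked-bar chart of start/stop codon classes per species,
    a presence/pseudogene/missing heatmap, and per-gene editing-ratio
    bars where pileup confirmation was run. Missing tables are skipped
    with a warning. Numbers are read back from the TSVs — the figures
    introduce nothing new.
    """
    import warnings

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    bundle = Path(bundle_dir)
    written: list[Path] = []

    edit_path = bundle / "editing.tsv"
    if edit_path.exists():
        df = pd.read_csv(edit_path, sep="\t", comment="#")
        if not df.empty:
            fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
            for ax, kind in zip(axes, ("start", "stop")):
                sub = df[df["kind"] == kind]
                pct = (
                    sub.groupby(["species", "class"]).size().unstack(fill_value=0)
                )
                pct = pct.div(pct.sum(axis=1), axis=0) * 100
                bottom = np.zeros(len(pct))
                for klass, color in (
                    ("abnormal", "#1f77b4"), ("normal", "#ff7f0e"), ("other", "#7f7f7f"),
                ):
                    vals = pct.get(klass, pd.Series(0, index=pct.index)).to_numpy()
                    ax.bar(pct.index, vals, bottom=bottom, label=klass, color=color)
                    bottom += vals
                ax.set_title(f"{kind} codons")
                ax.set_ylabel("% of surveyed genes")
                ax.tick_params(axis="x", rotation=90)
            axes[0].legend()
            fig.tight_layout()
            p = bundle / f"editing_classes.{fmt}"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)

            conf = df[(df["class"] == "abnormal") & (df["edit_ratio"] != "")]
            conf = conf.dropna(subset=["edit_ratio"])
            if not conf.empty:
                fig, ax = plt.subplots(figsize=(max(6, len(conf) * 0.25), 3.5))
                labels = conf["gene"] + ":" + conf["kind"].str[0]
                ax.bar(labels, conf["edit_ratio"].astype(float), color="#ff7f0e")
                ax.set_ylabel("edited read fraction T/(C+T)")
                ax.tick_params(axis="x", rotation=90)
                fig.tight_layout()
                p = bundle / f"editing_ratios.{fmt}"
                fig.savefig(p)
                plt.close(fig)
                written.append(p)
    else:
        warnings.warn("editing.tsv missing; editing figures skipped")

    matrix_path = bundle / "matrix.tsv"
    if matrix_path.exists():
        m = pd.read_csv(matrix_path, sep="\t", index_col=0)
        code_of = {"present": 2, "pseudogene": 1, "missing": 0}
        codes = m.map(lambda v: code_of.get(v, 0))
        fig, ax = plt.subplots(
            figsize=(max(6, codes.shape[1] * 0.18), max(2, codes.shape[0] * 0.35))
        )
        ax.imshow(codes.to_numpy(), aspect="auto", cmap="Blues", vmin=0, vmax=2)
        ax.set_yticks(range(codes.shape[0]), codes.index)
        ax.set_xticks(range(codes.shape[1]), codes.columns, rotation=90, fontsize=5)
        fig.tight_layout()
        p = bundle / f"presence_matrix.{fmt}"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)
    else:
        warnings.warn("matrix.tsv missing; heatmap skipped")
    return written
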