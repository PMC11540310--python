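"""File formats, configuration and result writing.

Genotypes travel either as phased VCF (GT with the ``|`` separator) or as
a plain TSV dialect with one row per marker: ``chrom``, ``pos_bp``, then
two haplotype columns per individual (``<id>.0``, ``<id>.1``).  Both
round-trip exactly.  Run configuration is YAML with strict keys, and
results are written as tidy TSVs plus a JSON manifest sufficient to
reproduce the run bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .founders import FounderPanel
from .genome import PhasedPopulation
from .program import ProgramConfig, SimulationLog


def read_phased_genotypes(path, fmt: str | None = None) -> FounderPanel:
    """Read phased genotypes from VCF or the TSV dialect (auto-detected
    from the extension when ``fmt`` is None)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format: {fmt!r}")


def _read_vcf(path: Path) -> FounderPanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    chroms, pos, h0_rows, h1_rows = [], [], [], []
    for var in vcf:
        h0, h1 = [], []
        for s, gt in zip(ids, var.genotypes):
            if len(gt) != 3:
                raise ValueError(
                    f"record {var.CHROM}:{var.POS} sample {s}: not diploid")
            a0, a1, phased = gt
            if not phased:
                raise ValueError(
                    f"record {var.CHROM}:{var.POS} sample {s}: genotype is unphased")
            if a0 < 0 or a1 < 0:
                raise ValueError(
                    f"record {var.CHROM}:{var.POS} sample {s}: missing call")
            h0.append(a0)
            h1.append(a1)
        chroms.append(var.CHROM)
        pos.append(var.POS)
        h0_rows.append(h0)
        h1_rows.append(h1)
    pop = PhasedPopulation(hap0=np.array(h0_rows, dtype=np.int8).T,
                           hap1=np.array(h1_rows, dtype=np.int8).T, ids=ids)
    return FounderPanel(population=pop, chrom=np.array(chroms),
                        pos_bp=np.array(pos, dtype=np.int64), provenance="imported")


def _read_tsv(path: Path) -> FounderPanel:
    df = pd.read_csv(path, sep="\t")
    hap_cols = [c for c in df.columns if c not in ("chrom", "pos_bp")]
    ids = []
    for c in hap_cols[::2]:
        if not c.endswith(".0"):
            raise ValueError(f"malformed haplotype column {c!r}")
        ids.append(c[:-2])
    h = df[hap_cols].to_numpy(dtype=np.int8).T  # (2n, L)
    pop = PhasedPopulation(hap0=h[0::2], hap1=h[1::2], ids=ids)
    return FounderPanel(population=pop, chrom=df["chrom"].to_numpy(),
                        pos_bp=df["pos_bp"].to_numpy(), provenance="imported")


def write_phased_tsv(panel: FounderPanel, path) -> None:
    cols = {"chrom": panel.chrom, "pos_bp": panel.pos_bp}
    for i, name in enumerate(panel.population.ids):
        cols[f"{name}.0"] = panel.population.hap0[i]
        cols[f"{name}.1"] = panel.population.hap1[i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_phased_vcf(panel: FounderPanel, path) -> None:
    pop = panel.population
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=cpsim{__version__}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(pop.ids) + "\n")
        for j in range(panel.n_markers):
            gts = "\t".join(f"{pop.hap0[i, j]}|{pop.hap1[i, j]}"
                            for i in range(pop.n_individuals))
            fh.write(f"{panel.chrom[j]}\t{panel.pos_bp[j]}\tM{j}\tA\tT\t.\tPASS\t.\tGT\t"
                     + gts + "\n")


def write_model_tsv(model, path) -> None:
    """Dump a fitted prediction model: header block of variance components
    and intercept, then one row per marker effect."""
    with open(path, "w") as fh:
        fh.write(f"#sigma_u2\t{float(model.sigma_u2)!r}\n")
        fh.write(f"#sigma_e2\t{float(model.sigma_e2)!r}\n")
        fh.write(f"#mu\t{float(model.mu)!r}\n")
        fh.write("marker\tbeta\n")
        for l, b in enumerate(model.beta_hat):
            fh.write(f"{l}\t{float(b)!r}\n")


def read_model_tsv(path) -> dict:
    """Load a model dump; returns variance components, intercept and beta_hat."""
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, val = line[1:].rstrip("\n").split("\t")
            header[key] = float(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    header["beta_hat"] = df["beta"].to_numpy()
    return header


def write_trait_tsv(trait, path) -> None:
    """One row per marker: index, causal flag, true effect."""
    qtn = set(int(q) for q in trait.qtn_indices)
    pd.DataFrame({
        "marker": np.arange(len(trait.beta)),
        "is_qtn": [int(l in qtn) for l in range(len(trait.beta))],
        "beta": trait.beta,
    }).to_csv(path, sep="\t", index=False)


def write_phenotypes_tsv(ids, phen, path) -> None:
    pd.DataFrame({"id": list(ids), "u": phen.u, "y": phen.y}).to_csv(
        path, sep="\t", index=False)


def load_config(path) -> ProgramConfig:
    """Load a YAML config; unknown keys are an error, missing keys take the
    full-scale defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of parameter names to values")
    valid = {f.name for f in dataclasses.fields(ProgramConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ProgramConfig(**raw)


def write_results(log: SimulationLog, outdir) -> None:
    """Tidy per-cycle metric TSVs plus a machine-readable manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for t, (gp, s2, rates) in enumerate(zip(log.gpic, log.sigma2, log.allele_rates)):
        rows.append((t, "gpic", gp))
        rows.append((t, "sigma2", s2))
        rows.append((t, "fixed_favorable", rates[0]))
        rows.append((t, "fixed_negative", rates[1]))
        rows.append((t, "non_fixed", rates[2]))
    for t in sorted(log.gi8):
        rows.append((t, "gi8", log.gi8[t]))
    pd.DataFrame(rows, columns=["cycle", "metric", "value"]).to_csv(
        outdir / "metrics.tsv", sep="\t", index=False)

    plan_rows = []
    for rec in log.plans:
        for i, j in rec["pairs"]:
            plan_rows.append((rec["cycle"], rec["strategy"], i, j, rec["objective"],
                              rec["feasible"], rec.get("dsel", ""), rec.get("he_t", "")))
    pd.DataFrame(plan_rows, columns=["cycle", "strategy", "parent_a", "parent_b",
                                     "objective", "feasible", "dsel", "he_t"]
                 ).to_csv(outdir / "plans.tsv", sep="\t", index=False)

    i8_rows = [(t, k, v) for t in sorted(log.inbred8_u)
               for k, v in enumerate(log.inbred8_u[t])]
    pd.DataFrame(i8_rows, columns=["cycle", "line", "u"]).to_csv(
        outdir / "inbred8.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "config": log.config.to_dict(),
        "baseline_u": log.baseline_u,
        "sigma_g2_init": log.sigma_g2_init,
        "he0": log.he0,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
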