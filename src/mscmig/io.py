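"""File formats: alignments, control files, traces, annotated gene trees.

Sequence labels follow the ``species^individual`` convention, so a locus
file is self-describing given the species tree.  Multi-locus PHYLIP files
are blocks separated by blank lines, each block starting with
``n_seq n_sites``.  All writers emit a header comment carrying the seed
and a configuration hash so outputs are traceable; every writer has a
matching reader and the pair round-trips exactly.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import MCMCSettings, Trace, hpd_interval
from .model import GeneTree, Locus, MigrationSpec, ParamSet, PriorSpec
from .species import SpeciesTree

__all__ = [
    "ALPHABET",
    "encode_seqs",
    "decode_seqs",
    "read_loci",
    "write_phylip",
    "read_phylip",
    "write_fasta",
    "read_fasta",
    "ControlConfig",
    "read_control",
    "parse_control",
    "serialize_control",
    "write_trace",
    "read_trace",
    "summarize",
    "gene_tree_to_newick",
    "gene_tree_from_newick",
]

ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(ALPHABET)}


def encode_seqs(strings: list[str]) -> np.ndarray:
    """DNA strings to integer codes (4 = gap/ambiguity, treated as missing)."""
    n = len(strings)
    m = len(strings[0]) if n else 0
    out = np.full((n, m), 4, dtype=np.int8)
    for i, s in enumerate(strings):
        if len(s) != m:
            raise ValueError("sequences must have equal length")
        for j, ch in enumerate(s.upper()):
            out[i, j] = _CODE.get(ch, 4)
    return out


def decode_seqs(codes: np.ndarray) -> list[str]:
    return ["".join(ALPHABET[c] if c < 4 else "-" for c in row)
            for row in codes]


# ---------------------------------------------------------------------------
# alignments


def write_phylip(loci: list[Locus], path) -> None:
    """Multi-locus PHYLIP: blank-line separated blocks."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{len(loc.names)} {loc.n_sites}\n")
            for name, row in zip(loc.names, decode_seqs(loc.seqs)):
                fh.write(f"{name}  {row}\n")
            fh.write("\n")


def read_phylip(path, h: float = 1.0) -> list[Locus]:
    text = Path(path).read_text()
    blocks = [b for b in re.split(r"\n\s*\n", text) if b.strip()]
    loci = []
    for bi, block in enumerate(blocks):
        lines = [ln for ln in block.splitlines() if ln.strip()]
        head = lines[0].split()
        if len(head) != 2:
            raise ValueError(f"locus {bi + 1}: malformed PHYLIP header "
                             f"{lines[0]!r}")
        n_seq, n_sites = int(head[0]), int(head[1])
        if len(lines) - 1 != n_seq:
            raise ValueError(f"locus {bi + 1}: expected {n_seq} sequences, "
                             f"found {len(lines) - 1}")
        names, seqs = [], []
        for ln in lines[1:]:
            parts = ln.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"locus {bi + 1}: malformed line {ln!r}")
            names.append(parts[0])
            seqs.append(parts[1].replace(" ", ""))
        codes = encode_seqs(seqs)
        if codes.shape[1] != n_sites:
            raise ValueError(f"locus {bi + 1}: header says {n_sites} sites, "
                             f"sequences have {codes.shape[1]}")
        loci.append(Locus(names=names, seqs=codes, h=h,
                          label=f"locus{bi + 1}"))
    return loci


def write_fasta(locus: Locus, path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(locus.names, decode_seqs(locus.seqs)):
            fh.write(f">{name}\n{row}\n")


def read_fasta(path, h: float = 1.0, label: str = "") -> Locus:
    names, seqs, cur = [], [], []
    for ln in Path(path).read_text().splitlines():
        if ln.startswith(">"):
            names.append(ln[1:].strip().split()[0])
            if cur:
                seqs.append("".join(cur))
                cur = []
        elif ln.strip():
            cur.append(ln.strip())
    if cur:
        seqs.append("".join(cur))
    if len(names) != len(seqs):
        raise ValueError("malformed FASTA")
    return Locus(names=names, seqs=encode_seqs(seqs), h=h,
                 label=label or Path(path).stem)


def read_loci(paths, fmt: str = "phylip", h: float = 1.0) -> list[Locus]:
    """Load loci from one multi-locus PHYLIP file or several FASTA files."""
    if fmt == "phylip":
        if isinstance(paths, (str, Path)):
            return read_phylip(paths, h=h)
        out = []
        for p in paths:
            out.extend(read_phylip(p, h=h))
        return out
    if fmt == "fasta":
        if isinstance(paths, (str, Path)):
            paths = [paths]
        return [read_fasta(p, h=h) for p in paths]
    raise ValueError(f"unknown alignment format {fmt!r}")


def check_labels(loci: list[Locus], stree: SpeciesTree) -> None:
    """Every sequence name must be species^individual with a known species."""
    tips = set(stree.labels[: stree.n_tips])
    for loc in loci:
        for name in loc.names:
            sp = name.split("^")[0]
            if sp not in tips:
                raise ValueError(
                    f"sequence {name!r} in {loc.label or 'locus'}: species "
                    f"tag {sp!r} not among the species-tree tips")


# ---------------------------------------------------------------------------
# control files


@dataclass
class ControlConfig:
    """Parsed control file for an inference, simulation or test run."""

    tree: str = ""
    species: list[str] = field(default_factory=list)
    migration: list[tuple[str, str]] = field(default_factory=list)
    seqfile: str = ""
    outfile: str = "out"
    seed: int = 1
    # gamma priors (shape, rate)
    thetaprior: tuple[float, float] = (2.0, 100.0)
    tauprior: tuple[float, float] = (2.0, 100.0)
    migprior: tuple[float, float] = (2.0, 10.0)
    # simulation truth (optional; label -> value)
    theta: dict[str, float] = field(default_factory=dict)
    tau: dict[str, float] = field(default_factory=dict)
    migrate: dict[tuple[str, str], float] = field(default_factory=dict)
    # run block
    n_iter: int = 2000
    burnin: int = 500
    thin: int = 1
    kernel: str = "extended"
    # sampling design
    n_seq: int = 4
    n_loci: int = 100
    n_sites: int = 500
    heredity: float = 1.0

    _KEYS = {
        "tree", "species", "migration", "seqfile", "outfile", "seed",
        "thetaprior", "tauprior", "migprior", "theta", "tau", "migrate",
        "n_iter", "burnin", "thin", "kernel", "n_seq", "n_loci", "n_sites",
        "heredity",
    }

    def species_tree(self) -> SpeciesTree:
        return SpeciesTree.from_newick(self.tree)

    def migration_spec(self, stree: SpeciesTree | None = None) -> MigrationSpec:
        return MigrationSpec(stree or self.species_tree(), self.migration)

    def prior_spec(self) -> PriorSpec:
        return PriorSpec(theta_shape=self.thetaprior[0],
                         theta_rate=self.thetaprior[1],
                         tau_shape=self.tauprior[0],
                         tau_rate=self.tauprior[1],
                         mig_shape=self.migprior[0],
                         mig_rate=self.migprior[1])

    def settings(self) -> MCMCSettings:
        return MCMCSettings(n_iter=self.n_iter, burnin=self.burnin,
                            thin=self.thin, tau_kernel=self.kernel)

    def params(self, stree: SpeciesTree, mig: MigrationSpec) -> ParamSet:
        """Simulation truth assembled from the theta/tau/migrate blocks."""
        theta = np.zeros(stree.n_nodes)
        tau = np.zeros(stree.n_nodes)
        for lab, v in self.theta.items():
            theta[stree.node(lab)] = v
        for lab, v in self.tau.items():
            tau[stree.node(lab)] = v
        M = np.zeros(mig.n_entries)
        for (s, j), v in self.migrate.items():
            M[mig.index(s, j)] = v
        return ParamSet(tau=tau, theta=theta, M=M)

    def hash(self) -> str:
        payload = {k: (sorted((str(kk), vv) for kk, vv in v.items())
                       if isinstance(v, dict) else v)
                   for k, v in sorted(self.__dict__.items())
                   if not k.startswith("_")}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def parse_control(text: str) -> ControlConfig:
    """Parse bpp-flavoured ``key = value`` lines; ``#`` starts a comment."""
    cfg = ControlConfig()
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', "
                             f"got {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        if key not in ControlConfig._KEYS:
            raise ValueError(f"line {lineno}: unknown key {key!r}")
        multi = key in ("migration", "theta", "tau", "migrate")
        if key in seen and not multi:
            raise ValueError(f"line {lineno}: duplicate key {key!r}")
        seen.add(key)
        try:
            _assign(cfg, key, val)
        except (ValueError, IndexError) as e:
            raise ValueError(f"line {lineno}: bad value for {key!r}: {e}") \
                from None
    return cfg


def _assign(cfg: ControlConfig, key: str, val: str) -> None:
    parts = val.split()
    if key == "tree":
        cfg.tree = val
    elif key == "species":
        cfg.species = parts
    elif key == "migration":
        cfg.migration.append((parts[0], parts[1]))
        if len(parts) > 2:
            cfg.migrate[(parts[0], parts[1])] = float(parts[2])
    elif key in ("seqfile", "outfile", "kernel"):
        setattr(cfg, key, val)
    elif key in ("seed", "n_iter", "burnin", "thin", "n_seq", "n_loci",
                 "n_sites"):
        setattr(cfg, key, int(val))
    elif key == "heredity":
        cfg.heredity = float(val)
    elif key in ("thetaprior", "tauprior", "migprior"):
        setattr(cfg, key, (float(parts[0]), float(parts[1])))
    elif key == "theta":
        cfg.theta[parts[0]] = float(parts[1])
    elif key == "tau":
        cfg.tau[parts[0]] = float(parts[1])
    elif key == "migrate":
        cfg.migrate[(parts[0], parts[1])] = float(parts[2])


def serialize_control(cfg: ControlConfig) -> str:
    out = _io.StringIO()
    out.write(f"tree = {cfg.tree}\n")
    if cfg.species:
        out.write(f"species = {' '.join(cfg.species)}\n")
    for s, j in cfg.migration:
        rate = cfg.migrate.get((s, j))
        out.write(f"migration = {s} {j}"
                  + (f" {rate:g}" if rate is not None else "") + "\n")
    if cfg.seqfile:
        out.write(f"seqfile = {cfg.seqfile}\n")
    out.write(f"outfile = {cfg.outfile}\n")
    out.write(f"seed = {cfg.seed}\n")
    for key in ("thetaprior", "tauprior", "migprior"):
        a, b = getattr(cfg, key)
        out.write(f"{key} = {a:g} {b:g}\n")
    for lab, v in cfg.theta.items():
        out.write(f"theta = {lab} {v:g}\n")
    for lab, v in cfg.tau.items():
        out.write(f"tau = {lab} {v:g}\n")
    for key in ("n_iter", "burnin", "thin"):
        out.write(f"{key} = {getattr(cfg, key)}\n")
    out.write(f"kernel = {cfg.kernel}\n")
    for key in ("n_seq", "n_loci", "n_sites"):
        out.write(f"{key} = {getattr(cfg, key)}\n")
    out.write(f"heredity = {cfg.heredity:g}\n")
    return out.getvalue()


def read_control(path) -> ControlConfig:
    return parse_control(Path(path).read_text())


# ---------------------------------------------------------------------------
# traces and summaries


def write_trace(trace: Trace, path) -> None:
    """Tab-separated samples with a comment header (seed, acceptance)."""
    with open(path, "w") as fh:
        fh.write(f"# seed = {trace.seed}\n")
        acc = " ".join(f"{k}:{v:.3f}" for k, v in trace.acceptance.items())
        fh.write(f"# acceptance = {acc}\n")
        trace.samples.to_csv(fh, sep="\t", index=False,
                             float_format="%.10g")


def read_trace(path) -> Trace:
    seed = None
    with open(path) as fh:
        pos = fh.tell()
        header_lines = []
        line = fh.readline()
        while line.startswith("#"):
            header_lines.append(line)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t").astype(np.float64)
    for ln in header_lines:
        m = re.match(r"#\s*seed\s*=\s*(\d+)", ln)
        if m:
            seed = int(m.group(1))
    return Trace(samples=df, acceptance={}, settings=MCMCSettings(),
                 seed=seed)


def summarize(trace: Trace, prob: float = 0.95) -> pd.DataFrame:
    """Posterior mean, median and HPD interval per parameter column."""
    rows = []
    for col in trace.param_names:
        x = trace[col]
        if np.ptp(x) == 0.0:
            lo = hi = float(x[0])
        else:
            lo, hi = hpd_interval(x, prob)
        rows.append({"param": col, "mean": float(x.mean()),
                     "median": float(np.median(x)),
                     "hpd_lo": lo, "hpd_hi": hi})
    return pd.DataFrame(rows).set_index("param")


# ---------------------------------------------------------------------------
# annotated gene-tree Newick (migration events as comment tags)


def gene_tree_to_newick(g: GeneTree, stree: SpeciesTree) -> str:
    """Newick with absolute node times and per-edge migration events.

    Node comments carry ``[&t=<age>,pop=<label>]``; edges with migration
    events list them oldest-last as ``mig=<time>:<src>:<dst>`` entries
    separated by ``|`` (times absolute, populations by label).
    """
    out = _io.StringIO()

    def tag(v: int) -> str:
        bits = [f"t={g.time[v]:.12g}", f"pop={stree.labels[int(g.node_pop[v])]}"]
        if g.edge_events[v]:
            evs = "|".join(
                f"{t:.12g}:{stree.labels[int(s)]}:{stree.labels[int(j)]}"
                for t, s, j in g.edge_events[v])
            bits.append(f"mig={evs}")
        return "[&" + ",".join(bits) + "]"

    def rec(v: int) -> None:
        if g.children[v, 0] >= 0:
            out.write("(")
            rec(int(g.children[v, 0]))
            out.write(",")
            rec(int(g.children[v, 1]))
            out.write(")")
        else:
            out.write(g.labels[v])
        out.write(tag(v))

    rec(g.root)
    out.write(";")
    return out.getvalue()


_TOKEN = re.compile(r"\(|\)|,|;|[^(),;\[\]]+|\[&[^\]]*\]")


def gene_tree_from_newick(text: str, stree: SpeciesTree) -> GeneTree:
    """Inverse of :func:`gene_tree_to_newick` (exact round trip)."""
    tokens = [t for t in _TOKEN.findall(text.strip()) if t and t != ";"]
    # first pass: collect tips in order
    tip_names = []
    for i, tok in enumerate(tokens):
        if tok not in "(),," and not tok.startswith("[&"):
            prev = tokens[i - 1] if i else "("
            if prev in "(,":
                tip_names.append(tok)
    n_tips = len(tip_names)
    tip_species = np.array([stree.node(nm.split("^")[0])
                            for nm in tip_names], dtype=np.int64)
    g = GeneTree(n_tips, tip_names, tip_species)
    next_internal = [n_tips]
    tip_iter = iter(range(n_tips))
    pos = [0]

    def parse_tag(v: int) -> None:
        tok = tokens[pos[0]]
        if not tok.startswith("[&"):
            raise ValueError("missing annotation tag")
        pos[0] += 1
        for piece in tok[2:-1].split(","):
            key, val = piece.split("=", 1)
            if key == "t":
                g.time[v] = float(val)
            elif key == "pop":
                g.node_pop[v] = stree.node(val)
            elif key == "mig":
                for ev in val.split("|"):
                    t, s, j = ev.split(":")
                    g.edge_events[v].append(
                        [float(t), float(stree.node(s)),
                         float(stree.node(j))])

    def node() -> int:
        tok = tokens[pos[0]]
        if tok == "(":
            pos[0] += 1
            left = node()
            assert tokens[pos[0]] == ","
            pos[0] += 1
            right = node()
            assert tokens[pos[0]] == ")"
            pos[0] += 1
            v = next_internal[0]
            next_internal[0] += 1
            g.children[v, 0] = left
            g.children[v, 1] = right
            g.parent[left] = v
            g.parent[right] = v
            parse_tag(v)
            return v
        # tip
        pos[0] += 1
        v = next(tip_iter)
        if tip_names[v] != tok:
            raise ValueError("tip order mismatch")
        parse_tag(v)
        return v

    g.root = node()
    g.parent[g.root] = -1
    return g
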