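"""Seeded synthetic fixtures for every pipeline stage.

ChIP signal per track is modelled as a zero-inflated log-normal: a gene
has signal 0 with probability ``zero_fraction``, otherwise a log-normal
draw — mimicking real tracks where many genes show very low but
detectable signal and a heavy right tail carries the true binding.  One
track can carry *planted* enrichment: the query genes' signals on that
track are shifted by ``effect`` so the recovery of the planted factor is a
measurable property.  Peak fixtures place one narrowPeak wholly inside
each gene's domain so matrix building reproduces the intended matrix
exactly, and ranked-list fixtures interpolate between a perfect and a
random ordering for the evaluation module.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneListSet
from .matrix_builder import (
    DomainSpec,
    GeneAnnotation,
    MagicMatrix,
    TrackMeta,
)


@dataclass
class SyntheticScenario:
    """Parameters of a planted-enrichment simulation.

    ``effect`` is multiplicative on nonzero signals by default (3.0 means
    planted query genes carry 3× signal on the planted track; 0 or 1 is
    the null); ``effect_mode="additive"`` adds ``effect`` to all planted
    query signals instead.  ``background_size``/``coregulation_bias``
    optionally make the true background a co-regulated subset of the
    matrix universe: background genes carry ``coregulation_bias``-fold
    signal on every track, emulating the correlation between expression
    and ChIP signal that makes a bespoke background list matter.
    """

    n_genes: int = 2000
    n_tracks: int = 50
    zero_fraction: float = 0.6
    lognorm_mu: float = 1.0
    lognorm_sigma: float = 1.0
    planted_track: int = 0
    effect: float = 3.0
    effect_mode: str = "multiplicative"
    query_size: int = 100
    background_size: int | None = None
    coregulation_bias: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_fraction < 1.0:
            raise ValueError("zero_fraction must be in [0, 1)")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.effect_mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")
        if self.query_size > self.n_genes:
            raise ValueError("query_size cannot exceed n_genes")
        if not 0 <= self.planted_track < self.n_tracks:
            raise ValueError("planted_track out of range")
        if self.background_size is not None:
            if not self.query_size <= self.background_size <= self.n_genes:
                raise ValueError("background_size must be in [query_size, n_genes]")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticScenario":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _track_metas(n: int) -> list[TrackMeta]:
    return [TrackMeta(factor_name=f"TF{i:03d}", description="synthetic") for i in range(n)]


def make_matrix_fixture(
    scenario: SyntheticScenario,
) -> tuple[MagicMatrix, GeneListSet]:
    """Simulate a signal matrix plus background/query lists under a scenario.

    All tracks are exchangeable draws from the zero-inflated log-normal
    except the planted track, where the query genes' signals are shifted
    by ``effect``.  With a co-regulated background, the background genes
    (a random subset containing the query) have every track scaled by the
    bias factor, and the query is drawn from the background.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    genes = _gene_names(sc.n_genes)
    metas = _track_metas(sc.n_tracks)

    nonzero = rng.random((sc.n_genes, sc.n_tracks)) >= sc.zero_fraction
    values = np.where(
        nonzero,
        rng.lognormal(sc.lognorm_mu, sc.lognorm_sigma, (sc.n_genes, sc.n_tracks)),
        0.0,
    )

    if sc.background_size is not None:
        bg_idx = rng.choice(sc.n_genes, size=sc.background_size, replace=False)
        values[bg_idx, :] *= sc.coregulation_bias
        query_idx = rng.choice(bg_idx, size=sc.query_size, replace=False)
        background = [genes[i] for i in sorted(bg_idx)]
    else:
        query_idx = rng.choice(sc.n_genes, size=sc.query_size, replace=False)
        background = list(genes)

    t = sc.planted_track
    if sc.effect_mode == "multiplicative":
        if sc.effect > 0:
            values[query_idx, t] *= sc.effect
    else:
        values[query_idx, t] += sc.effect

    matrix = MagicMatrix(
        values=pd.DataFrame(values, index=genes, columns=[m.track_id for m in metas]),
        tracks=metas,
    )
    lists = GeneListSet(
        background=background,
        queries={"query": [genes[i] for i in sorted(query_idx)]},
        background_name="background",
    )
    return matrix, lists


#: gene layout constants for peak fixtures (bp)
_GENE_LENGTH = 2000
_GENE_SPACING = 50_000


def make_annotation_fixture(n_genes: int, chrom: str = "chr1") -> list[GeneAnnotation]:
    """Evenly spaced genes far enough apart that domains never overlap."""
    out = []
    for i, sym in enumerate(_gene_names(n_genes)):
        start = 10_000 + i * _GENE_SPACING
        out.append(
            GeneAnnotation(
                symbol=sym,
                chrom=chrom,
                strand="+" if i % 2 == 0 else "-",
                tx_start=start,
                tx_end=start + _GENE_LENGTH,
            )
        )
    return out


def make_peak_fixture(
    scenario: SyntheticScenario,
    out_dir: str | Path,
    domain: DomainSpec | None = None,
) -> tuple[Path, Path, MagicMatrix]:
    """Write annotation + manifest + narrowPeak files realising a scenario.

    One peak is placed wholly inside each gene's domain with signalValue
    equal to the intended matrix cell (no peak for 0 cells), so running
    the matrix builder on the emitted files reproduces the intended matrix
    exactly.  Returns (annotation path, manifest path, intended matrix).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, _ = make_matrix_fixture(scenario)
    ann = make_annotation_fixture(scenario.n_genes)

    ann_path = out_dir / "annotation.tsv"
    pd.DataFrame(
        {
            "symbol": [g.symbol for g in ann],
            "chrom": [g.chrom for g in ann],
            "strand": [g.strand for g in ann],
            "tx_start": [g.tx_start for g in ann],
            "tx_end": [g.tx_end for g in ann],
        }
    ).to_csv(ann_path, sep="\t", index=False)

    peaks_dir = out_dir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for j, meta in enumerate(matrix.tracks):
        fname = f"track_{j:03d}.narrowPeak"
        with open(peaks_dir / fname, "w") as fh:
            for g in ann:
                v = matrix.values.at[g.symbol, meta.track_id]
                if v <= 0:
                    continue
                # 200 bp peak at the gene body start: inside every domain kind
                # except '-' strand promoters, so anchor strand-aware at TSS
                anchor = g.tx_start if g.strand == "+" else g.tx_end - 200
                fh.write(
                    "\t".join(
                        [
                            g.chrom, str(anchor), str(anchor + 200),
                            f"{meta.track_id}_{g.symbol}", "0", ".",
                            f"{v:.17g}", "-1", "-1", "100",
                        ]
                    )
                    + "\n"
                )
        manifest_rows.append(
            {
                "file_path": f"peaks/{fname}",
                "factor": meta.factor_name,
                "description": meta.description,
                "engineered": 0,
            }
        )
    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)
    return ann_path, manifest_path, matrix


def make_ranked_fixture(
    n_factors: int,
    n_positives: int,
    quality: float,
    seed: int = 0,
) -> tuple[list[str], set[str]]:
    """Ranked factor list with known positives, at a given ordering quality.

    quality = 1 places all positives first; quality = 0 is a uniform
    shuffle; intermediate values mix a perfect ordering score with uniform
    noise.  Deterministic under ``seed``.
    """
    if not 0.0 <= quality <= 1.0:
        raise ValueError("quality must be in [0, 1]")
    if not 0 < n_positives < n_factors:
        raise ValueError("need 0 < n_positives < n_factors")
    rng = np.random.default_rng(seed)
    names = [f"TF{i:03d}" for i in range(n_factors)]
    positives = set(names[:n_positives])
    ideal = np.array([1.0 if f in positives else 0.0 for f in names])
    noise = rng.random(n_factors)
    scores = quality * ideal + (1.0 - quality) * noise
    order = np.argsort(-scores, kind="stable")
    return [names[i] for i in order], positives
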