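"""Model / Results interface over the EM machinery.

``IsoformFunctionModel`` holds the corpus data (genes, gene-level GO
annotations, sequences, domain evidence); ``fit`` runs the per-subontology
mini-batch EM and returns an ``IsoformFunctionResults`` carrying the final
assignments, the fitted quadratic coefficients, the sigma traces and a
text summary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as iomod
from .annotations import NAMESPACES, AssignmentMatrix, combine_assignments
from .driver import CorpusInputs, EMConfig, EMState, coverage_report, run_full
from .emcore import QuadraticModel
from .evaluation import ConfusionSummary, confusion_vs_curation


class IsoformFunctionModel:
    """Distributes gene-level GO annotations to individual isoforms.

    Parameters mirror :class:`~isofunc.driver.CorpusInputs`; the
    constructors ``from_files`` (standard file formats) and
    ``from_synthetic`` (a planted corpus) are the usual entry points.
    """

    def __init__(self, inputs: CorpusInputs) -> None:
        self.inputs = inputs

    @classmethod
    def from_files(cls, gaf, obo, fasta, domains, ipr2go) -> "IsoformFunctionModel":
        return cls(CorpusInputs.from_files(gaf, obo, fasta, domains, ipr2go))

    @classmethod
    def from_synthetic(cls, truth, sequences: Mapping[str, str] | None = None,
                       seed_fraction: float = 0.3, seed: int = 0) -> "IsoformFunctionModel":
        from .synthetic import domain_seed, simulate_sequences

        dom, i2g = domain_seed(truth, seed_fraction=seed_fraction, seed=seed)
        if sequences is None:
            sequences = simulate_sequences(truth, seed=seed)
        inputs = CorpusInputs(
            genes=truth.genes,
            tg=truth.tg.copy(),
            domains=dom,
            ipr2go=i2g,
            term_namespaces=truth.term_namespaces,
            sequences=dict(sequences),
        )
        return cls(inputs)

    def fit(
        self,
        config: EMConfig | None = None,
        namespaces: Sequence[str] = NAMESPACES,
        providers: Mapping[str, object] | None = None,
        out_dir: str | Path | None = None,
    ) -> "IsoformFunctionResults":
        results = run_full(
            self.inputs, config=config, namespaces=namespaces,
            providers=providers, out_dir=out_dir,
        )
        return IsoformFunctionResults(self, results, config or EMConfig())


class IsoformFunctionResults:
    """Fitted assignments, coefficients and convergence traces."""

    def __init__(
        self,
        model: IsoformFunctionModel,
        results: dict[str, tuple[AssignmentMatrix | None, EMState | None]],
        config: EMConfig,
    ) -> None:
        self.model = model
        self.config = config
        self.assignments: dict[str, AssignmentMatrix] = {
            ns: am for ns, (am, _) in results.items() if am is not None
        }
        self.states: dict[str, EMState] = {
            ns: st for ns, (_, st) in results.items() if st is not None
        }

    # -- estimates --------------------------------------------------------
    @property
    def params(self) -> pd.DataFrame:
        rows = {
            ns: st.model.coefficients for ns, st in self.states.items()
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["beta0", "beta1", "beta2"]
        )

    def quadratic(self, namespace: str) -> QuadraticModel:
        return self.states[namespace].model

    def predict_similarity(self, tau, namespace: str):
        """Model-mean standardized similarity at a shared-term count."""
        return self.states[namespace].model.predict(tau)

    def sigma_trace(self, namespace: str) -> list[float]:
        return list(self.states[namespace].sigma_trace)

    # -- annotations ------------------------------------------------------
    def annotation_frame(self) -> pd.DataFrame:
        return combine_assignments(self.assignments.values())

    def n_annotated_isoforms(self) -> int:
        df = self.annotation_frame()
        return df["isoform_id"].nunique()

    def n_terms_used(self) -> int:
        return self.annotation_frame()["go_id"].nunique()

    def coverage(self, namespace: str) -> pd.DataFrame:
        return coverage_report(self.assignments[namespace])

    def score_curation(self, records) -> dict[str, ConfusionSummary]:
        return {
            ns: confusion_vs_curation(am, records)
            for ns, am in self.assignments.items()
        }

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for ns, am in self.assignments.items():
            iomod.write_isoform_annotations(am, out / f"isoform_annotations_{ns}.tsv")
            pd.DataFrame(
                {
                    "iteration": range(len(self.states[ns].sigma_trace)),
                    "sigma": self.states[ns].sigma_trace,
                }
            ).to_csv(out / f"sigma_trace_{ns}.tsv", sep="\t", index=False)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        lines = ["Isoform function inference (mini-batch EM)", "=" * 44]
        df = self.annotation_frame()
        lines.append(f"annotated isoforms : {df['isoform_id'].nunique()}")
        lines.append(f"distinct GO terms  : {df['go_id'].nunique()}")
        lines.append(f"total annotations  : {len(df)}")
        for ns in NAMESPACES:
            if ns not in self.states:
                continue
            st = self.states[ns]
            b0, b1, b2 = st.model.coefficients
            lines.append("")
            lines.append(f"[{ns}]")
            lines.append(
                f"  beta0={b0:+.4f}  beta1={b1:+.4f}  beta2={b2:+.4f}  (sigma=1 fixed)"
            )
            lines.append(
                f"  E-step iterations={max(len(st.sigma_trace) - 1, 0)}  "
                f"final sigma={st.sigma_trace[-1]:+.4f}"
            )
            am = self.assignments[ns]
            lines.append(
                f"  set bits={int(am.bits.sum())} of "
                f"{int(am.candidate_mask.sum())} candidate cells"
            )
        return "\n".join(lines)

    def plot_trace(self, namespace: str, ax=None):
        """Sigma (sum of per-subset mean pair log-likelihood) vs iteration."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        trace = self.sigma_trace(namespace)
        ax.plot(range(len(trace)), trace, marker="o", ms=3)
        ax.set_xlabel("E-step iteration")
        ax.set_ylabel(r"$\sigma_i$ (summed mean pair log-likelihood)")
        ax.set_title(f"{namespace} convergence trace")
        return ax

    def plot_similarity_fit(self, namespace: str, ax=None):
        """Mean observed similarity per shared-term count of the last E
        pass, with the fitted quadratic overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        st = self.states[namespace]
        taus = np.concatenate([t for _, t in st.last_pass]) if st.last_pass else np.array([])
        scores = (
            np.concatenate([tab.std for tab, _ in st.last_pass])
            if st.last_pass
            else np.array([])
        )
        if taus.size:
            uniq = np.unique(taus)
            means = [scores[taus == u].mean() for u in uniq]
            ax.plot(uniq, means, "o", label="mean observed")
            grid = np.linspace(0, float(uniq.max()), 50)
            ax.plot(grid, st.model.predict(grid), "-", label="quadratic fit")
        ax.set_xlabel("shared GO terms")
        ax.set_ylabel("standardized similarity")
        ax.legend()
        return ax
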