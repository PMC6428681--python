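"""Rare coding-variant burden, gene-set enrichment, and de novo meta-analysis.

A reusable implementation of the analysis stack of targeted case-control
sequencing studies of candidate gene panels: Firth penalized-likelihood
burden regression with ancestry/sex/sequencing-wave covariates, mutation-
class and allele-frequency filtering, per-gene mutation-rate de novo
enrichment (Poisson), permutation and random-gene-set empirical nulls,
fixed-effects / pooled meta-analysis, Fisher combination of case-control and
trio evidence, and a synthetic cohort generator so every stage can be
exercised without access to restricted genotype data.
"""

__version__ = "0.1.0"

from .filtering import (  # noqa: F401,E402
    burden_counts,
    class_mask,
    classify_composite,
    frequency_filter,
    rate_excess,
)
from .firth import (  # noqa: F401,E402
    AssociationResult,
    FirthFit,
    burden_test,
    firth_fit,
    wald_ci,
    wald_pvalue,
)
from .denovo import (  # noqa: F401,E402
    DeNovoResult,
    denovo_set_test,
    expected_count,
    poisson_upper_p,
)
from .meta import (  # noqa: F401,E402
    CORRECTION_LEDGER,
    bonferroni,
    cochran_q,
    combine_evidence,
    exclude_overlap,
    fisher_combined,
    fixed_effects,
    one_sided,
    pooled_meta,
    se_from_ci,
    z_difference,
)
from .resampling import (  # noqa: F401,E402
    PermutationResult,
    permutation_pvalue,
    permute_burden_test,
    random_geneset_null,
)
from .simulate import (  # noqa: F401,E402
    SynthConfig,
    expected_case_count,
    synth_burden_table,
    synth_cohort,
    synth_genes,
    synth_rate_table,
    synth_trios,
)
from .genesets import (  # noqa: F401,E402
    AnalysisPlan,
    GeneSetDefinition,
    PlanRow,
    partition_by_pli,
    restrict_paralog_flags,
    run_plan,
    single_gene_scan,
)
from .pipeline import RunConfig, run  # noqa: F401,E402
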