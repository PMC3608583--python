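"""Published reference inputs for the DR2 allele / peptide systems.

The table below carries the published solvated-interaction-energy binding
free energies for the two HLA-DR2 alleles (predisposing DRB1*15:01,
protective DRB1*16:01) bound to the self peptide MBP 85-98 and the viral
peptide EBNA-1 400-413, together with the IC50 and MBP-relative ratio values
printed alongside them.  The free energies are *inputs* to the IC50
conversion arithmetic implemented in :mod:`pmhcgroove.thermo`; nothing here
is computed by this package.

Note: for the *15:01 rows, the printed IC50 cells are mutually swapped with
respect to the printed free energies (applying dG = kB T ln IC50 at 310 K to
-16.7 kcal/mol gives ~1.7e-3 nM, and to -16.0 gives ~5.2e-3 nM, the reverse
of the published pairing).  The *16:01 rows and both ratio columns are
self-consistent.  The table reproduces the published cells verbatim and
leaves reconciliation to the caller.
"""
from __future__ import annotations

import pandas as pd


def dr2_sie_free_energies() -> pd.DataFrame:
    """Published per-complex binding free energies and derived IC50 cells.

    Columns: allele, peptide, dg (kcal/mol), dg_sd (kcal/mol),
    ic50_nM_published, ratio_published (IC50 / IC50 of the allele's MBP row).
    """
    rows = [
        ("DRB1*15:01", "MBP", -16.7, 0.6, 5.2e-3, 1.0),
        ("DRB1*15:01", "EBNA-1", -16.0, 0.7, 1.7e-3, 3.0),
        ("DRB1*16:01", "MBP", -17.5, 0.7, 4.6e-4, 1.0),
        ("DRB1*16:01", "EBNA-1", -12.2, 0.7, 2.5, 5434.0),
    ]
    return pd.DataFrame(
        rows,
        columns=["allele", "peptide", "dg", "dg_sd", "ic50_nM_published", "ratio_published"],
    )
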