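"""Cognate neuropeptide-precursor / receptor pairing.

A neuropeptide precursor (NPP) gene and a neuropeptide-selective GPCR
(NP-GPCR) gene are *cognate* when the processed peptide binds the
receptor; the link is carried as a shared ``cognate_group`` key in the
gene panels (e.g. Sst and Sstr2 both under "SST").  The pairing test
asks, area-wide: for each NPP gene passing the expression filter, is
at least one cognate receptor gene also expressed anywhere in the
area?  A stricter type-resolved mode restricts the receptor to types
where the NPP itself is expressed above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import FormatError, GenePanel
from .signatures import DeltaTable, SignatureMatrix

__all__ = ["PairingReport", "cognate_pairing"]


@dataclass
class PairingReport:
    """Per-NPP pairing outcome plus the area-level summary."""

    table: pd.DataFrame  # index NPP symbol
    n_npp_expressed: int
    n_paired: int

    @property
    def paired_fraction(self) -> float:
        if self.n_npp_expressed == 0:
            return float("nan")
        return self.n_paired / self.n_npp_expressed

    def summary(self) -> dict:
        return {
            "n_NPP_expressed": self.n_npp_expressed,
            "n_paired": self.n_paired,
            "paired_fraction": self.paired_fraction,
        }


def cognate_pairing(
    delta_table_npp: DeltaTable,
    delta_table_npgpcr: DeltaTable,
    panel: GenePanel,
    signature_npp: SignatureMatrix | None = None,
    signature_npgpcr: SignatureMatrix | None = None,
    expression_threshold: float | None = None,
) -> PairingReport:
    """Pair expressed NPP genes with expressed cognate NP-GPCR genes.

    The two delta tables hold the genes that passed the expression
    filter; the panel supplies the cognate dictionary.  An NPP with no
    ``cognate_group`` key is reported unresolvable and excluded from
    the paired-fraction denominator.  Supplying the two signature
    matrices plus a threshold switches on the type-resolved mode, which
    additionally requires a cognate receptor above threshold in at
    least one type where the NPP itself is above threshold.
    """
    pan = panel.table.set_index("symbol")
    npp_rows = pan[pan["category"] == "NPP"]
    if npp_rows.empty:
        raise FormatError("panel contains no NPP genes")
    receptor_rows = pan[pan["category"] == "NP_GPCR"]
    expressed_npp = set(delta_table_npp.symbols)
    expressed_rec = set(delta_table_npgpcr.symbols)

    type_resolved = signature_npp is not None and signature_npgpcr is not None
    if type_resolved and expression_threshold is None:
        raise FormatError("type-resolved pairing needs an expression_threshold")

    records = []
    n_expressed = n_paired = 0
    for symbol, row in npp_rows.iterrows():
        group = row["cognate_group"]
        cognates = (
            receptor_rows.index[receptor_rows["cognate_group"] == group].tolist()
            if group
            else []
        )
        expressed = symbol in expressed_npp
        resolvable = bool(group)
        cognates_expressed = [c for c in cognates if c in expressed_rec]
        if type_resolved and expressed and cognates_expressed:
            npp_types = signature_npp.means.loc[symbol]
            hot = npp_types.index[npp_types > expression_threshold]
            cognates_expressed = [
                c
                for c in cognates_expressed
                if (signature_npgpcr.means.loc[c, hot] > expression_threshold).any()
            ]
        paired = expressed and resolvable and len(cognates_expressed) > 0
        if expressed and resolvable:
            n_expressed += 1
            n_paired += int(paired)
        records.append(
            {
                "symbol": symbol,
                "cognate_group": group,
                "expressed": expressed,
                "resolvable": resolvable,
                "cognate_receptors": "|".join(cognates),
                "n_cognates_expressed": len(cognates_expressed),
                "paired": paired,
            }
        )
    table = pd.DataFrame(records).set_index("symbol")
    return PairingReport(table=table, n_npp_expressed=n_expressed, n_paired=n_paired)
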