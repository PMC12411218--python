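# Table schemas

All pipeline tables are tidy CSV files with a header row.  `ppx.synthdata.
read_table`/`write_table` validate against these schemas and raise
`SchemaError` naming the offending column or row.

## trials

One row per tactile-stimulation trial.

| column | type | notes |
| --- | --- | --- |
| participant_id | str | unique within the study |
| cohort | str | neutral, infection or fearful (vaccine has no trials) |
| session | str | `baseline` or `second` |
| condition | str | `T` (unisensory tactile) or `VT` (visuo-tactile) |
| distance | int 1–5 or empty | D1 = near … D5 = far; empty for T trials |
| delay_index | int 1–5 | tactile stimulus delay slot |
| rt_ms | float > 0 | reaction time in milliseconds |

## marker_panel

One row per participant × timepoint for an immune marker family
(`markers_<panel>_<timepoint>.csv`; panels: `ilc_frequency`,
`ilc_activation`, `ilc1_activation`, `ilc2_activation`, `ilcp_activation`).

| column | type | notes |
| --- | --- | --- |
| participant_id | str | |
| cohort | str | one of the four cohorts |
| timepoint | str | `baseline` or `post` |
| *feature columns* | float | frequency panel: `total_ILC_pct_lymph`, `ILC1_pct_ILC`, `ILC2_pct_ILC`, `ILCP_pct_ILC` (subset percentages sum to 100); activation panels: `% positive` per marker (CD25, CD27, CD69, NKp30, NKp44, NKp46, KLRG1, PD1, HLA-DR) |

## mediator_panel

One row per participant × timepoint for a serum mediator family
(`mediators_<family>_<timepoint>.csv`; families: `hormones` (8 features),
`eicosanoids` (20), `neuroinflammation` (the 13 named factors VILIP-1,
CCL2, sTREM-2, BDNF, TGFb1, VEGF, IL-6, sTREM-1, b-NGF, IL-18, TNF, sRAGE,
CX3CL1)).  Same identifier columns as marker_panel; feature columns are
non-negative concentrations (arbitrary units in the synthetic data; record
real units in accompanying metadata).

## index_table

Output of `ppx indices` and `ppx.indices.index_table`.

| column | type | notes |
| --- | --- | --- |
| participant_id | str | |
| cohort | str | |
| score | float | first-principal-component score (sign convention in the JSON sidecar) |

## EEG epochs

One CSV matrix per participant × condition under `eeg/`
(`<participant>_<condition>.csv`): rows = channels, columns = samples,
values in µV; `eeg/times_ms.csv` holds the shared sample times relative to
tactile onset.  Conditions: `T`, `VT_near_A`, `VT_near_B`, `VT_far_A`,
`VT_far_B` (A/B = the two avatar sets).

## ground_truth.json

Generator-planted quantities for verification only: per-participant latents
(h, e, nf, activation), outcome-function parameters, planted PPS boundaries
per cohort/session, planted EEG effect window, seed.
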