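# Visit CSV schema

One row per patient-visit, UTF-8, comma-separated, header row required.
Rows are written sorted by (`patient_id`, `month_index`).

| column | type | meaning |
|---|---|---|
| `patient_id` | string | opaque patient identifier, unique per patient |
| `month_index` | real ≥ 0 | months since the patient's first visit; 0 at the first row of each patient, strictly increasing |
| `age_years` | real | age at the visit |
| `sex` | `M` / `F` | constant within a patient |
| *codebook columns* | 0/1 | one column per binary feature; the codebook is inferred as every column between `sex` and `activity_flag`, in order |
| `activity_flag` | 0/1 | SLEDAI-2K binarized: 0 = inactive, 1 = any activity |
| `sdi_score` | integer ≥ 0 | cumulative SLICC/ACR damage index; non-decreasing within a patient |

The default codebook written by the simulator (32 features, in order):
`aps, sjogren_syndrome, autoimmune_thyroiditis, fibromyalgia, dyslipidemia,
arterial_hypertension, renal_involvement, skin_involvement,
neurological_involvement, joint_involvement, hematological_involvement,
thrombosis, obstetrical_complications, anti_dsdna, anti_ssa, anti_ssb,
anti_sm, anti_rnp, anti_cardiolipin, anti_b2gpi, lupus_anticoagulant,
low_c3, low_c4, glucocorticoids, hydroxychloroquine, methotrexate,
azathioprine, cyclosporine, cyclophosphamide, mycophenolate, rituximab,
belimumab`

Validation (`sledamage validate <csv>`) rejects missing columns, non-binary
flag values, decreasing SDI, unsorted or non-zero-starting visit times,
changing sex, and duplicate patient ids.  Missing values are not permitted;
adapters for real data must impute upstream.
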