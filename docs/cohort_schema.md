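# Cohort CSV schema

UTF-8, comma-separated, `.` decimal point, one header row, one row per
subject.  Empty numeric cells mean "not measured" (absent) and are never
interpreted as zero.  Booleans are `true`/`false`.

| column | type | meaning |
|---|---|---|
| `subject_id` | string | unique subject identifier |
| `cohort` | int | 1 (2:2:1 randomization) or 2 (1:1 randomization) |
| `arm` | enum | `VOR50`, `VOR10`, `IVO500`, `IVO250`, `UNTREATED` |
| `treated_presurgery` | bool | received study drug before resection |
| `missed_doses_2wk` | int | doses missed in the two weeks before surgery |
| `midh1_confirmed` | bool | mIDH1-R132H confirmed in resected tissue |
| `tissue_sufficient` | bool | enough tumor tissue for the 2-HG assay |
| `dosing_correct` | bool | pre-surgery dosing per protocol |
| `tumor_2hg` | float ≥ 0 | tumor 2-HG, µg per g tissue (may be empty) |
| `cellularity` | float ∈ (0,1] | tumor-cell fraction from H&E (may be empty) |
| `c_5hmc`, `c_5mc`, `c_c` | float ≥ 0 | nucleoside counts: 5hmC, 5mC, unmodified C |
| `ki67_pct` | float | percent Ki-67-positive cells |
| `cd3_density`, `cd8_density` | float ≥ 0 | T-cell densities, cells per mm² |
| `baseline_spd` | float > 0 | postoperative baseline SPD, cm² (empty = no residual disease) |
| `no_residual_disease` | bool | complete resection |
| `lesion_days` | `;`-joined ints | MRI visit days, strictly increasing |
| `lesion_spd` | `;`-joined floats | SPD at each visit, cm² |

The external-control table shares the numeric conventions with columns
`sample_id`, `idh_status` (`WT` or `mIDH1`) and `tumor_2hg`.
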