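# 83-column per-gene feature schema, grouped.
#
# Editable: the pipeline validates that exactly 83 uniquely named features are
# listed and that the group sizes are 35/2/19/16/4/2/5. Constraint columns
# follow gnomAD v2.1.1 constraint-table naming; expression columns encode
# tissue group (Brain = non-cerebellar brain metavalue, Cereb = cerebellar
# metavalue, Nerve), sex stratum (F/M/all) and developmental age group
# (Pre, Post1 = birth..4y, Post2 = >4y, Post = all postnatal).
constraint:
  - loeuf
  - mis_z
  - syn_z
  - lof_z
  - pli
  - pnull
  - prec
  - oe_lof
  - oe_lof_lower
  - oe_mis
  - oe_mis_lower
  - oe_mis_upper
  - oe_mis_pphen
  - oe_syn
  - oe_syn_lower
  - oe_syn_upper
  - obs_lof
  - exp_lof
  - obs_mis
  - exp_mis
  - obs_syn
  - exp_syn
  - obs_mis_pphen
  - exp_mis_pphen
  - mu_lof
  - mu_mis
  - mu_syn
  - possible_lof
  - possible_mis
  - possible_syn
  - max_af
  - classic_caf
  - obs_het_lof
  - obs_hom_lof
  - no_lofs
conservation:
  - exon_score
  - promoter_score
expression_adult:
  - tau
  - tau_1
  - tau_2
  - mean_Brain_F
  - var_Brain_F
  - mean_Brain_M
  - var_Brain_M
  - mean_Cereb_F
  - var_Cereb_F
  - mean_Cereb_M
  - var_Cereb_M
  - mean_Nerve_F
  - var_Nerve_F
  - mean_Nerve_M
  - var_Nerve_M
  - mean_Brain_all
  - var_Brain_all
  - mean_Cereb_all
  - var_Cereb_all
expression_developmental:
  - mean_Pre_F
  - var_Pre_F
  - mean_Pre_M
  - var_Pre_M
  - mean_Post1_F
  - var_Post1_F
  - mean_Post1_M
  - var_Post1_M
  - mean_Post2_F
  - var_Post2_F
  - mean_Post2_M
  - var_Post2_M
  - mean_Post_F
  - var_Post_F
  - mean_Post_M
  - var_Post_M
structure:
  - cds_length
  - exon_count
  - transcript_length
  - promoter_cpg_density
position:
  - dist_centromere
  - dist_telomere
paralogue:
  - n_paralogues
  - n_close_paralogues
  - max_target_pct
  - max_query_pct
  - mean_target_pct
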