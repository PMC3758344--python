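sample_id,tissue,braf,nras,cdkn2a,tp53,dtic_response,age,sex,stage,site
MM01,melanoma,V600E,wild_type,unknown,unknown,responder,55,male,III,trunk
MM02,melanoma,V600E,wild_type,unknown,unknown,responder,58,male,IV,trunk
MM03,melanoma,V600E,wild_type,unknown,unknown,responder,61,male,IV,trunk
MM04,melanoma,V600E,wild_type,unknown,unknown,responder,64,male,IV,trunk
MM05,melanoma,V600E,wild_type,unknown,unknown,non_responder,67,female,IV,trunk
MM06,melanoma,V600E,wild_type,unknown,unknown,non_responder,55,female,IV,trunk
MM07,melanoma,V600E,wild_type,unknown,unknown,non_responder,58,female,IV,trunk
MM08,melanoma,V600E,wild_type,unknown,unknown,non_responder,61,female,IV,lower_extremity
MM09,melanoma,V600E,wild_type,unknown,unknown,non_responder,64,female,IV,lower_extremity
MM10,melanoma,V600E,wild_type,unknown,unknown,non_responder,67,female,IV,no_primary_detected
MM11,melanoma,wild_type,Q61,unknown,unknown,responder,52,male,IV,lower_extremity
MM12,melanoma,wild_type,Q61,unknown,unknown,responder,57,male,IV,lower_extremity
MM13,melanoma,wild_type,Q61,unknown,unknown,responder,62,male,IV,lower_extremity
MM14,melanoma,wild_type,Q61,unknown,unknown,responder,67,male,IV,lower_extremity
MM15,melanoma,wild_type,Q61,unknown,unknown,responder,52,male,IV,upper_extremity
MM16,melanoma,wild_type,Q61,unknown,unknown,responder,57,male,IV,upper_extremity
MM17,melanoma,wild_type,wild_type,unknown,unknown,responder,62,male,IV,upper_extremity
MM18,melanoma,wild_type,wild_type,unknown,unknown,responder,67,female,IV,head
MM19,melanoma,wild_type,wild_type,unknown,unknown,responder,52,female,IV,head
MM20,melanoma,wild_type,wild_type,unknown,unknown,non_responder,57,female,IV,head
MM21,melanoma,wild_type,wild_type,unknown,unknown,non_responder,62,female,IV,trunk
MM22,melanoma,wild_type,wild_type,unknown,unknown,non_responder,67,female,IV,trunk
MM23,melanoma,wild_type,wild_type,unknown,unknown,non_responder,52,female,IV,no_primary_detected
MM24,melanoma,wild_type,wild_type,unknown,unknown,non_responder,57,female,IV,no_primary_detected
MM25,melanoma,wild_type,wild_type,unknown,unknown,non_responder,62,female,IV,no_primary_detected
MM26,melanoma,unknown,wild_type,unknown,unknown,non_responder,63,male,IV,no_primary_detected
NS01,normal_skin,unknown,unknown,unknown,unknown,unknown,,,,
NS02,normal_skin,unknown,unknown,unknown,unknown,unknown,,,,
NS03,normal_skin,unknown,unknown,unknown,unknown,unknown,,,,
NS04,normal_skin,unknown,unknown,unknown,unknown,unknown,,,,
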