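lab,recording,ontology_id,term_label,granular_group,general_group
Lab-A,Dead,,"whole organism dead, abnormal",,
Lab-A,Delayed_hatch,,"hatching delayed, abnormal",delayed hatching,hatching defects
Lab-A,Jaw_malformation,,"ventral mandibular arch morphology, abnormal",jaw defects,head defects
Lab-A,Snout_malformation,,"snout malformed, abnormal",snout defects,head defects
Lab-A,Smaller_abnormal_eye_shape,,"eye decreased size, abnormal",eye defects,head defects
Lab-A,Curved_axis,,"axis curved, abnormal",axis defects,torso defects
Lab-A,Notochord_malformation,,"notochord morphology, abnormal",notochord defects,torso defects
Lab-A,Presence_of_head_Edema,,"heart edematous, abnormal",heart edema,heart defects
Lab-A,Yolk_sac_Edema,,"yolk edematous, abnormal",yolk edema,yolk defects
Lab-A,Yolk_opacity,ZP:0002198,"yolk opaque, abnormal",yolk opacity,yolk defects
Lab-B,DEAD,,"whole organism dead, abnormal",,
Lab-B,HATCH,,"hatching delayed, abnormal",delayed hatching,hatching defects
Lab-B,CRAN,,"ventral mandibular arch morphology, abnormal",jaw defects,head defects
Lab-B,CRAN,,"snout malformed, abnormal",snout defects,head defects
Lab-B,EYE_,,"eye decreased size, abnormal",eye defects,head defects
Lab-B,AXIS,,"axis curved, abnormal",axis defects,torso defects
Lab-B,AXIS,,"notochord morphology, abnormal",notochord defects,torso defects
Lab-B,EDEM,,"heart edematous, abnormal",heart edema,heart defects
Lab-B,EDEM,,"yolk edematous, abnormal",yolk edema,yolk defects
Lab-C,mortality,,"whole organism dead, abnormal",,
Lab-C,hatching_delay,,"hatching delayed, abnormal",delayed hatching,hatching defects
Lab-C,jaw__malformed,,"ventral mandibular arch morphology, abnormal",jaw defects,head defects
Lab-C,snout__malformed,,"snout malformed, abnormal",snout defects,head defects
Lab-C,eye__small,,"eye decreased size, abnormal",eye defects,head defects
Lab-C,body_axis__curved,,"axis curved, abnormal",axis defects,torso defects
Lab-C,notochord__abnormal,,"notochord morphology, abnormal",notochord defects,torso defects
Lab-C,Percardial_tissue__Edema,,"heart edematous, abnormal",heart edema,heart defects
Lab-C,Yolk_sac__Edema,,"yolk edematous, abnormal",yolk edema,yolk defects
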