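dataset,id,gender,age,time_poststroke,hand_dominance,stroke_type,affected_hemisphere,mri_report,lesion_level,brunnstrom_proximal,brunnstrom_distal,fma_pre,fma_post,tempa_pre,tempa_post,wmft_pre,wmft_post,true_condition,prediction
training,T01,M,72,15,R,I,L,brain stem,subcortical,3,3,23,37,-67,-46,26,37,F,
training,T02,M,68,12,R,H,L,thalamus intracerebral,subcortical,4,4,38,50,-48,-33,49,56,F,
training,T03,M,53,2,R,H,R,basal ganglion ICH,subcortical,3,2,13,26,-86,-78,31,38,F,
training,T04,M,59,1,R,I,R,MCA,cortical,5,5,59,66,-14,-6,67,73,F,
training,T05,M,50,5,R,H,L,basal ganglion ICH,subcortical,3,3,11,19,-72,-64,12,14,F,
training,T06,M,65,8,R,I,L,post part of MCA,cortical,5,4,42,43,-44,-27,55,54,F,
training,T07,M,59,12,R,I,L,MCA,cortical,5,4,35,42,-35,-40,46,43,F,
training,T08,F,33,6,R,I,R,MCA,cortical,2,2,9,8,-93,-87,20,29,F,
training,T09,M,69,3,R,H,L,thalamus,subcortical,5,6,42,53,-29,-20,64,66,F,
training,T10,F,60,1,R,I,R,MCA,cortical,2,2,13,26,-93,-84,31,41,F,
training,T11,M,62,13,R,I,L,basalganglia and thalamus,subcortical,3,2,15,17,-94,-76,35,36,F,
training,T12,M,65,5,R,H,L,"ICH, pons and midbrain",subcortical,5,5,52,61,-76,-49,39,47,F,
training,T13,F,75,4,R,I,R,MCA,cortical,4,5,36,52,-57,-29,43,57,F,
training,T14,M,27,2,L,H,L,Fronto-temporal regions,cortical,3,2,17,21,-69,-79,12,23,F,
training,T15,F,68,2,R,H,R,ICH thalamus,subcortical,4,5,31,40,-41,-35,54,61,F,
training,T16,M,63,2,R,I,L,MCA,cortical,2,1,8,9,-75,-86,21,36,F,
training,T17,M,57,2,R,H,L,putamen,subcortical,4,4,24,35,-64,-50,42,54,F,
training,T18,M,69,1,R,H,L,thalamus,subcortical,5,6,43,52,-33,-17,56,60,F,
training,T19,M,51,1,R,I,L,corona rediata,subcortical,4,2,22,31,-68,-54,42,49,F,
training,T20,M,39,15,R,H,L,ICH,subcortical,3,3,22,26,-70,-68,38,38,P,
training,T21,M,60,17,R,H,L,ICH putamen,subcortical,3,2,21,19,-79,-74,35,36,P,
training,T22,F,38,5,R,H,L,ICH thalamus,subcortical,4,4,45,49,-35,-25,57,59,P,
training,T23,M,58,4,R,I,R,MCA,cortical,5,5,35,40,-45,-36,50,55,P,
training,T24,F,44,10,L,I,L,MCA,cortical,5,4,36,38,-51,-46,51,53,P,
training,T25,M,64,12,R,H,R,thalamic and basal ganglia,subcortical,3,3,17,16,-93,-86,35,32,P,
training,T26,F,61,3,R,I,R,Fron-topartieal,cortical,4,4,36,42,-47,-39,48,52,P,
training,T27,F,79,1,R,I,R,paramedian area of the pons,subcortical,5,5,43,44,-26,-27,65,59,P,
training,T28,M,46,10,R,I,L,medulla,subcortical,5,5,43,44,-23,-28,62,65,P,
training,T29,M,50,9,R,I,R,MCA,cortical,5,4,51,52,-22,-21,67,64,P,
training,T30,M,28,9,L,H,L,Fronto-temporal regions,cortical,3,3,23,24,-82,-68,42,45,P,
training,T31,M,57,5,R,H,R,thalamus and brain stem ICH,subcortical,4,5,34,38,-65,-66,21,29,P,
training,T32,F,75,5,R,H,R,ICH thalamus,subcortical,4,5,33,31,-50,-49,42,46,P,
training,T33,M,54,4,R,I,L,ACA,subcortical,5,5,55,57,-7,-7,68,68,P,
training,T34,M,76,5,R,I,L,Psterior corona radiata,subcortical,3,5,31,25,-49,-43,50,57,P,
training,T35,F,49,20,R,I,R,middle and superior frontal lobe,cortical,5,4,35,37,-51,-55,46,49,P,
training,T36,M,58,12,R,H,R,"thalamus, corona vadiata, lentinucleus",subcortical,2,1,10,10,-57,-69,12,21,P,
training,T37,M,45,2,R,I,L,medulla,subcortical,5,5,42,44,-25,-26,63,65,P,
validation,V01,F,59,7,R,H,R,MCA,cortical,2,4,23,25,-88,-88,36,49.5,F,P
validation,V02,M,58,8,R,I,L,basalganglia and thalamus,subcortical,3,3,24,33,-105,-87,46,54,F,F
validation,V03,M,44,21,R,I,R,basal ganglia,subcortical,2,2,14,16,-104,-87,43,28,F,F
validation,V04,M,34,8,R,I,L,ganglion,subcortical,5,4,38,40,-81,-82,49,60,F,F
validation,V05,M,46,8,R,H,R,basal ganglion,subcortical,3,3,18,29,-86,-93,50,59,F,F
validation,V06,M,44,13,R,I,L,paramedian pontine,subcortical,4,5,50,56,-28,-7,68,71,F,F
validation,V07,M,60,1,R,I,R,posterior limb of internal capsule,subcortical,5,5,52,59,-15,-5,73,71,F,F
validation,V08,M,39,7,R,I,L,medial medulla and cerebellum,subcortical,5,4,38,39,-16,-14,72,83,F,F
validation,V09,M,60,6,R,I,L,caudate nucleus,subcortical,3,4,30,32,-75,-57,50,51,F,F
validation,V10,M,53,4,R,H,R,basal ganglion,subcortical,4,4,38,52,-63,-25,65,68,F,F
validation,V11,M,51,12,R,H,L,MCA,subcortical,3,4,22,29,-82,-79,40,40,F,F
validation,V12,F,27,7,R,I,R,basal ganglion,subcortical,4,5,33,34,-68,-65,46,45,P,P
validation,V13,M,64,16,R,I,R,MCA,cortical,3,3,21,22,-63,-63,37,37,P,F
validation,V14,M,55,5,R,I,R,mid brain to pons,subcortical,3,3,48,51,-60,-52,59,63,P,P
validation,V15,M,62,10,R,I,L,MCA,cortical,4,4,46,47,-42,-68,74,74,P,P
validation,V16,M,51,14,R,H,R,AVM; fronto-tempro-parietal,cortical,3,4,37,43,-44,-48,61,62,P,F
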