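# Brain-pathway catalog over the AAL-116 parcellation (33 definitions -> 59
# lateralized instances). The orbitofrontal loop carries its documented region
# sequence (orbitofrontal cortex -> caudate -> globus pallidus -> thalamus,
# closing back on the orbitofrontal cortex). The remaining region sequences are
# plausible anatomical reconstructions chosen so that every name resolves in
# the AAL-116 label set; substitute a curated catalog for real studies.
# Columns: name, domain, function, lateralization, closed, regions, reference.
# Bilateral/left/right rows use hemisphere-neutral names (suffixed _L/_R at
# expansion); 'special' rows list named variants with explicit region names.
name	domain	function	lateralization	closed	regions	reference
Dorsolateral prefrontal	cognition	Executive function	bilateral	true	Frontal_Mid;Caudate;Pallidum;Thalamus	Catani2008
Orbitofrontal	cognition	Decision making	bilateral	true	Frontal_Mid_Orb;Caudate;Pallidum;Thalamus	Catani2008
Medial prefrontal	cognition	Attention	bilateral	true	Frontal_Sup_Medial;Caudate;Pallidum;Thalamus	Catani2008
Anterior cingulate	cognition	Motivation	bilateral	true	Cingulum_Ant;Caudate;Pallidum;Thalamus	Mega1994
Papez	cognition	Memory storage	bilateral	true	Hippocampus;Thalamus;Cingulum_Ant;ParaHippocampal	Mega1994
Language(auditory)	cognition	Repeat spoken word	left	false	Heschl;Temporal_Sup;SupraMarginal;Frontal_Inf_Oper;Precentral	Bear2007
Language(visual)	cognition	Repeat written word	left	false	Calcarine;Occipital_Mid;Angular;Temporal_Sup;Frontal_Inf_Tri	Bear2007
Baumgartner (2011)	cognition	Fairness decisions	right	false	Frontal_Mid;Frontal_Inf_Tri;Insula	Baumgartner2011
Richardson (2011)	cognition	Efficient reading	bilateral	false	Temporal_Mid;Angular;Frontal_Inf_Tri	Richardson2011
Frey (2008)	cognition	Language	left	false	Frontal_Inf_Tri;Temporal_Sup;Parietal_Inf	Frey2008
Ji (2007)	cognition	Memory	bilateral	false	Hippocampus;ParaHippocampal;Temporal_Mid	Ji2007
Walton (2004)	cognition	Decision making	bilateral	false	Cingulum_Ant;Frontal_Med_Orb;Frontal_Sup_Medial	Walton2004
Van Schie (2004)	cognition	Error observation	bilateral	false	Cingulum_Mid;Supp_Motor_Area;Precentral	VanSchie2004
Turkeltaub (2003)	cognition	Reading	left	false	Fusiform;Temporal_Mid;Frontal_Inf_Oper	Turkeltaub2003
Default mode network	cognition	Spontaneous thought	special	false	PCC:Cingulum_Post_L;Cingulum_Post_R;Precuneus_L;Precuneus_R;Angular_L;Angular_R|vmPFC:Frontal_Med_Orb_L;Frontal_Med_Orb_R;Rectus_L;Rectus_R;Cingulum_Ant_L;Cingulum_Ant_R	Raichle2001
Benchenane (2010)	cognition	Learning	bilateral	false	Hippocampus;Frontal_Sup_Medial;Cingulum_Ant	Benchenane2010
Emotion(fear)	emotion	Fear conditioning	bilateral	false	Amygdala;Hippocampus;Frontal_Med_Orb	Bear2007
Emotion	emotion	Emotion processing	bilateral	false	Amygdala;Cingulum_Ant;Frontal_Med_Orb;Insula	Nolte2002
Emotion(expression)	emotion	Facial expression	bilateral	false	Fusiform;Amygdala;Frontal_Inf_Orb	Nolte2002
Orsini (2011)	emotion	Renewal of fear	bilateral	false	Hippocampus;Amygdala;Frontal_Med_Orb	Orsini2011
Krolak-Salmon (2004)	emotion	Fear spreading	left	false	Insula;Amygdala;Frontal_Inf_Orb;Temporal_Pole_Sup	KrolakSalmon2004
Motor	motor	Control of movement	bilateral	true	Precentral;Putamen;Pallidum;Thalamus	Nolte2002
Cerebellar	motor	Limb movement	bilateral	true	Precentral;Cerebelum_4_5;Thalamus	Bear2007
Visual	sensation	Vision sensation	bilateral	false	Thalamus;Calcarine;Cuneus;Lingual	Bear2007
Auditory	sensation	Hearing sensation	bilateral	false	Thalamus;Heschl;Temporal_Sup	Bear2007
Gustatory	sensation	Taste sensation	bilateral	false	Thalamus;Insula;Frontal_Inf_Oper	Bear2007
Somatosensory	sensation	Touch, pain	bilateral	false	Thalamus;Postcentral;Parietal_Sup	Bear2007
Olfactory	sensation	Smell sensation	bilateral	false	Olfactory;Amygdala;ParaHippocampal;Frontal_Med_Orb	Bear2007
Nitschke (2006)	sensation	Aversive taste	bilateral	false	Insula;Cingulum_Ant;Frontal_Med_Orb;Amygdala	Nitschke2006
Plailly (2008)	sensation	Attention to odor	bilateral	false	Olfactory;Insula;Frontal_Inf_Orb;Hippocampus	Plailly2008
Visual(dorsal)	recognition	Spatial vision	bilateral	false	Calcarine;Occipital_Sup;Parietal_Sup;Parietal_Inf	Bear2007
Visual(ventral)	recognition	Object recognition	bilateral	false	Calcarine;Lingual;Fusiform;Temporal_Inf	Bear2007
Druzgal (2001)	recognition	Face recognition	left	false	Fusiform;Frontal_Inf_Tri;Frontal_Mid	Druzgal2001
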