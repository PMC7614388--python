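section	substrate	product	regeneration	standard	verified	provenance
kinase	Ins1P	-	-	-	yes	dash
kinase	Ins3P	-		-	yes	blank_dash
kinase	Ins(1,4)P2	Ins(1,3,4)P3	++	**	yes	graded
kinase	Ins(1,3,4)P3	Ins(1,3,4,5)P4	+	*	yes	graded
kinase	Ins(1,4,5)P3	-		-	yes	blank_dash
kinase	Ins(1,4,6)P3	Ins(1,3,4,6)P4	+++	***	yes	graded
kinase	Ins(3,4,6)P3	Ins(1,3,4,6)P4	+	*	yes	graded
kinase	Ins(3,4,5)P3	Ins(3,4,5,6)P4		**	yes	standard_only
kinase	Ins(4,5,6)P3	-	-		yes	dash_blank
kinase	Ins(1,2,4,6)P4	-		-	yes	blank_dash
kinase	Ins(2,3,4,6)P4	-		-	yes	blank_dash
kinase	Ins(1,3,4,5)P4	-		-	yes	blank_dash
kinase	Ins(1,3,5,6)P4	-		-	yes	blank_dash
kinase	Ins(1,3,4,6)P4	-		-	yes	blank_dash
kinase	Ins(1,4,5,6)P4	Ins(1,3,4,5,6)P5	+++	**	yes	graded
kinase	Ins(3,4,5,6)P4	-		-	yes	blank_dash
kinase	Ins(1,2,3,4,5)P5	-	-		yes	dash_blank
kinase	Ins(1,2,3,5,6)P5	-	-		yes	dash_blank
kinase	Ins(1,2,3,4,6)P5	-	-		yes	dash_blank
kinase	Ins(1,3,4,5,6)P5	-	-		yes	dash_blank
kinase	Ins(1,2,4,5,6)P5	-	-		yes	dash_blank
kinase	Ins(2,3,4,5,6)P5	-	-		yes	dash_blank
kinase	Ins(1,2,3,4,5,6)P6	-	-		yes	dash_blank
phosphotransfer	Ins(1,3,4)P3	-	++		no	not_verified
phosphotransfer	Ins(1,4,6)P3	-	++		no	not_verified
phosphotransfer	Ins(1,3,4,6)P4	Ins(1,4,6)P3/Ins(3,4,6)P3	+++		yes	racemic_pair
phosphotransfer	Ins(1,4,5,6)P4	-	+		no	not_verified
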