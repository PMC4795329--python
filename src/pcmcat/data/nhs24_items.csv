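item_id,text,n_steps,difficulty,in_pool,routes
15,Were you ever bothered by noise at night from other patients?,1,2.17,1,
16,Were you ever bothered by noise at night from hospital staff?,1,1.84,1,
17,"In your opinion, how clean was the hospital room or ward that you were in?",3,-0.56,1,
18,How clean were the toilets and bathrooms that you used in the hospital?,3,-2.20,1,
19,Did you feel threatened during your stay in the hospital by other patients or visitors?,1,1.88,1,
20,Were hand-wash gels available for patients and visitors to use?,2,1.33,1,
21,How would you rate the hospital food?,3,-1.72,1,
22,Were you offered a choice of food?,2,-0.04,1,
23,Did you get enough help from staff to eat your meals?,2,0.98,1,
24,"When you had important questions to ask a doctor, did you get answers that you could understand?",2,-1.01,1,
25,Did you have confidence and trust in the doctors treating you?,2,-0.86,1,
26,Did doctors talk in front of you as if you weren't there?,2,-1.15,1,
27,"When you had important questions to ask a nurse, did you get answers that you could understand?",2,1.48,1,
28,Did you have confidence and trust in the nurses treating you?,2,1.26,1,
29,Did nurses talk in front of you as if you weren't there?,2,-1.46,1,
30,"In your opinion, were there enough nurses on duty to care for you in the hospital?",2,-1.40,1,
31,"Sometimes in a hospital, a member of staff will say one thing and another will say something quite different. Did this happen to you?",2,-1.22,1,
32,Were you involved as much as you wanted to be in decisions about your care and treatment?,2,0.56,1,
33,Did you have confidence in the decisions made about your condition or treatment?,2,-0.78,1,
34,How much information about your condition or treatment was given to you?,2,1.48,1,
35,Did you find someone on the hospital staff to talk to about your worries and fears?,2,-0.77,1,
36,Do you feel you got enough emotional support from hospital staff during your stay?,2,-0.75,1,
37,Were you given enough privacy when discussing your condition or treatment?,2,1.58,1,
38,Were you given enough privacy when being examined or treated?,2,-0.65,1,
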