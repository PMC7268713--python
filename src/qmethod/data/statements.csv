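id,text
1,Body constitution that can indicate the susceptibility to diseases
2,Ability to adapt to weather changes
3,Body weight
4,Spiritual appearance
5,Natural colour and appearance of face
6,Feeling of tiredness
7,Body strength of doing things
8,Feeling of discomfort
9,Feeling of pain
10,Desire of having food
11,Feeling of pressure
12,Feeling of depression
13,Feeling of anxiety
14,Tendency of being angry
15,Feeling of fear
16,Feeling of loneliness
17,Self-confidence
18,Ability to remain stable and peaceful in mood
19,Sleep quality
20,Ability to walk about
21,Ability to perform usual activities
22,Vision
23,Hearing
24,Ability to communicate with people
25,Ability to wash and dress oneself
26,Dependence on medication
27,State of sex life
28,Ability to think things clearly
29,Ability to perceive changes in surrounding and to respond swiftly
30,Ability to remember things
31,Ability to make decisions
32,Ability to concentrate
33,State of social relations
34,Ability to adapt to the social environment
35,Support from one's social network
36,Social morality
37,Life attitude
38,"""Breadth of mind"""
39,Regularity in daily life
40,Diet habits
41,Sense of satisfaction with life
42,Family medical history
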