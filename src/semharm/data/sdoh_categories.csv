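Category,Subcategory 1,Subcategory 2,Subcategory 3,Definition
Health,,,,"General category, anything ""medical"" or affecting the physiologic functioning of the body (i.e., physical) or mind (i.e., mental)."
Health,Physical,,,"Physiological (e.g. HIV testing), neurological (e.g., sleep)"
Health,Mental,,,"Psychiatry (emotion, mood, hallucination, nightmare, eating disorder, contemplating suicide/homicide, developmental/learning disabilities)"
Health,Mental,Psychological (Non-medical),,"Confidence or ability to complete the activities of daily living, stressors, attitude, meditation, understanding, comprehension, awareness, judgement, insight, object recall, self-help, life goals, life plan, sexual orientation (i.e., gender)"
Health,Mental,Behavioral,,"Addiction, losing control, behavioral therapy (group/individual)"
Health,Mental,Behavioral,Substance Use,"Role of substance use, treatment, detox, relapse"
Health,Mental,Behavioral,Gambling,Addicted to playing games of chance for money
Health,Mental,Behavioral,Sexual or Physical Abuse,"Violence to others/self, general violence/domestic violence, action/plan for homicide or suicide."
Family,,,,Group of adults and their children living together or with shared experiences
Family,Family History,,,"Family history of any illnesses, conditions, family of origin"
Family,Relationship,,,"Support system, sex (condom), relationship with children or living with children"
Family,Childhood Experience,,,"Experiences growing up, trauma, fear, foster care, upbring"
Family,Childcare Service,,,Childcare needs
Education,,,,Process of giving or receiving systematic instruction.
Education,Training,,,Vocational
Education,Language,,,Secondary Language
Education,School,,,"Learning style, educational plan, grade, education problems, educational goals, degree"
Education,Literacy,,,"Reading, writing, arithmetic"
Employment,,,,Condition of having paid work
Employment,Work,,,"Workplace, work environment"
Employment,Finances,,,"Income, salary"
Employment,Insurance,,,"Medicare, medicaid, private insurance"
Employment,Benefits,,,"Social security, disability, assistance (employment assistance program [eap], social assistance, etc)"
Housing,,,,Shelter or living quarters
Housing,Location,,,"Physical space (i.e., building, structure, homelessness)"
Housing,Roommates,,,"Household activities, number of people who live in households"
Housing,Community,,,"Neighborhood, county, transportation"
Leisure,,,,"Free time, hobbies, interests, activities"
Legal,,,,Related to or the process of the law
Legal,Legal History,,,"Court, prior conviction, prior arrest, sentencing"
Legal,Parole,,,Mandated treatment
Legal,Incarceration,,,"Jail, Prison"
Legal,Child Protective Services (CPS),,,Child protection against mistreatment
Demographics,,,,"Age, sex, race, ethnicity, primary language, zip code"
Military,,,,Relating to or the characteristic of the armed forces
Spirituality,,,,Quality of being concerned with human spirit or soul.
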