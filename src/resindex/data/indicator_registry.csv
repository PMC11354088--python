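id,name,theme,bric_domain,direction,source,year
living_alone,Living alone - percentage of households occupied by one person,Demographic,social,LOW_GOOD,ONS,2021
age_dependency,Age dependency ratio - population aged 0-16 and 65+ over population aged 17-64,Demographic,social,LOW_GOOD,ONS,2021
population_density,Population density - usual residents per square kilometre,Demographic,social,HIGH_GOOD,ONS,2021
inward_migration,Inward migration - percentage of population who are inward migrants in the last 12 months,Demographic,social,HIGH_GOOD,ONS,2021
imd_gap,Deprivation gap - population weighted mean difference in deprivation score between small areas,Equity,social,LOW_GOOD,OHID,2020
adult_skills,Adult skills - qualification index score of highest level of qualification,Education/skills,social,HIGH_GOOD,ONS,2021
english_language,Language - speaks English as a first language or very well,Language/communication,social,HIGH_GOOD,ONS,2021
digital_propensity,Digital propensity index - population weighted average of online-first census returns,Language/communication,social,HIGH_GOOD,ONS,2021
car_availability,Car availability - percentage of households with no access to a car or van,Transport,social,LOW_GOOD,ONS,2021
food_insecurity,Food insecurity - modelled percentage of households experiencing hunger or struggling to access food,Food,social,LOW_GOOD,Moretti et al.,2021
employment,Employment - percentage of population aged 16-64 in employment,Labour market,economic,HIGH_GOOD,ONS,2021
economic_inactivity,Economic inactivity - percentage of population aged 16-64 economically inactive,Labour market,economic,LOW_GOOD,ONS,2021
employment_sectors,Employment sector diversity - distribution of employment across sectors,Labour market,economic,HIGH_GOOD,ONS,2021
gini_index,Gini index - inequality in household income within districts,Equity,economic,LOW_GOOD,ONS,2020
gender_pay_gap,Gender pay gap - mean difference in average hourly earnings between men and women,Equity,economic,LOW_GOOD,ONS,2020-2022
household_income,Gross disposable household income,Income/savings/debt,economic,HIGH_GOOD,ONS,2021
child_poverty,Percentage of children in absolute low-income families,Income/savings/debt,economic,LOW_GOOD,OHID,2021/22
fuel_poverty,Fuel poverty - modelled proportion of households in fuel poverty,Income/savings/debt,economic,LOW_GOOD,BEIS,2020
sme_loans,Loans and overdrafts to small and medium enterprises per capita,Commerce/retail,economic,HIGH_GOOD,UK Finance,2021
high_street_vibrancy,High street vibrancy - change in percentage of vacant retail units,Commerce/retail,economic,LOW_GOOD,CDRC,2019-2023
housing_affordability,Housing affordability - ratio of lower quartile house price to lower quartile earnings,Housing,economic,LOW_GOOD,ONS,2021
productivity,Productivity - nominal smoothed gross value added per hour worked,Economic output,economic,HIGH_GOOD,ONS,2021
public_health_grant,Municipal spending - public health grant allocation per head of population,Local government,institutional,HIGH_GOOD,MHCLG,2021/22
core_spending_power,Total core spending power per dwelling,Local government,institutional,HIGH_GOOD,DLUHC,2021/22
core_reserves,Non-ringfenced reserves as percentage of service spend,Local government,institutional,HIGH_GOOD,DLUHC,2022/23
lottery_funding,Community lottery funding per head of population,Civic engagement,institutional,HIGH_GOOD,National Lottery Community Fund,2021-2023
pupil_absence,Pupil absences - percentage of school sessions missed,Education/skills,institutional,LOW_GOOD,OHID,2021/22
school_quality,School quality - percentage rated good or outstanding of those inspected,Education/skills,institutional,HIGH_GOOD,DfE,2022
overcrowding,Household overcrowding - percentage with occupancy rating below -1,Housing,infrastructure,LOW_GOOD,Health index,2020
temporary_accommodation,Households in temporary accommodation,Housing,infrastructure,LOW_GOOD,MHCLG/DLUHC,2020-2021
travel_time_services,Average minimum travel time to key services by public transport,Transport,infrastructure,LOW_GOOD,DfT,2019
distance_leisure,Distance to sports and leisure facilities,Transport,infrastructure,LOW_GOOD,Health index,2020
broadband,Broadband - percentage of premises without access above 10 Mbit/s fixed broadband,Language/communication,infrastructure,LOW_GOOD,Health index,2020
private_outdoor_space,Private outdoor space - percentage of addresses with private outdoor space,Green space/forests,environmental,HIGH_GOOD,Health index,2020
green_space_access,Access to green space - average distance to nearest park or public garden,Green space/forests,environmental,LOW_GOOD,ONS,2020
air_pollution,Air pollution - territorial carbon dioxide emissions within local authority influence,Waste/pollution,environmental,LOW_GOOD,BEIS,2020
population_churn,Population churn - proportion of households with change in occupiers,Demographic,community_capital,LOW_GOOD,CDRC,2016-2021
charities,Registered charities per 100000 population,Civic engagement,community_capital,HIGH_GOOD,Charity Commission,2022
community_assets,Registered assets of community value per 100000 population,Civic engagement,community_capital,HIGH_GOOD,Plunkett UK,2022
electoral_turnout,Electoral turnout - percentage who voted in the 2019 general election,Political engagement,community_capital,HIGH_GOOD,House of Commons Library,2019
religious_affiliation,Religious affiliation - percentage who are religious adherents,Religion,community_capital,HIGH_GOOD,ONS,2021
life_satisfaction,Life satisfaction - average happiness score of survey respondents,Health/well-being,community_capital,HIGH_GOOD,Health index,2020
culture_spending,Municipal budget allocation for cultural and related services per head,Culture/sports,community_capital,HIGH_GOOD,DLUHC,2021/22
noise_complaints,Crude rate of noise complaints per 1000 population,Other,community_capital,LOW_GOOD,Health index,2020
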